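"""TPM normalization and cohort-relative expression context.

Expression of the genes of interest (MYB, MYBL1, QKI) in a case is judged
against a large reference cohort of CNS tumors profiled on the same
platform: the case's TPM is placed at its midrank percentile of the cohort
distribution, and group-level contrasts are summarized with the
probability-of-superiority statistic (the proportion of case-versus-cohort
pairs in which the case value is larger, ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortComparison",
    "counts_to_tpm",
    "cohort_percentile",
    "qki_cohort_contrast",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample non-negative expression matrix.

    ``values`` is a pandas DataFrame indexed by gene symbol with sample ids
    as columns.  ``unit`` is ``"raw_counts"`` or ``"TPM"``; TPM columns sum
    to 1e6 over the full gene set.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in {"raw_counts", "TPM"}:
            raise ValueError(f"unit must be 'raw_counts' or 'TPM', got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CohortComparison:
    """One gene's case value placed within the reference cohort."""

    gene: str
    case_tpm: float
    cohort_median: float
    percentile: float
    elevated: bool


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: dict[str, int] | pd.Series) -> ExpressionMatrix:
    """Convert raw counts to transcripts per kilobase million.

    Per sample: ``rate_g = counts_g / length_kb_g`` and
    ``TPM_g = 1e6 * rate_g / sum(rates)``.  Gene length is the summed exonic
    length in nucleotides.
    """
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing gene length(s): {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if (counts.values < 0).any():
        raise ValueError("counts must be >= 0")
    col_sums = counts.sum(axis=0)
    dead = list(col_sums.index[col_sums == 0])
    if dead:
        raise ValueError(f"all-zero sample(s): {dead}")

    rates = counts.div(lengths / 1000.0, axis=0)
    tpm = rates.div(rates.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(values=tpm, unit="TPM")


def cohort_percentile(
    gene: str,
    case_value: float,
    cohort: ExpressionMatrix,
    threshold: float = 90.0,
) -> CohortComparison:
    """Midrank percentile of a case value within the cohort distribution.

    ``percentile = 100 * (#cohort < value + 0.5 * #equal) / n``; the case is
    called elevated when the percentile reaches ``threshold``.
    """
    if gene not in cohort.values.index:
        raise KeyError(f"gene {gene!r} absent from cohort matrix")
    vals = cohort.values.loc[gene].to_numpy(dtype=float)
    n = vals.size
    pct = 100.0 * (np.sum(vals < case_value) + 0.5 * np.sum(vals == case_value)) / n
    return CohortComparison(
        gene=gene,
        case_tpm=float(case_value),
        cohort_median=float(np.median(vals)),
        percentile=float(pct),
        elevated=bool(pct >= threshold),
    )


def qki_cohort_contrast(
    study_cases: ExpressionMatrix,
    cohort: ExpressionMatrix,
    gene: str = "QKI",
) -> dict:
    """Rank-based contrast of one gene between study cases and the cohort.

    Returns group medians and the probability of superiority: the fraction
    of (case, cohort) pairs where the case value exceeds the cohort value,
    with tied pairs counted half.  Computed from midranks of the pooled
    sample (equivalent to the Mann-Whitney U divided by n1*n2), so it is
    exact under ties without enumerating pairs.
    """
    for name, mat in (("study", study_cases), ("cohort", cohort)):
        if gene not in mat.values.index:
            raise KeyError(f"gene {gene!r} absent from {name} matrix")
    x = study_cases.values.loc[gene].to_numpy(dtype=float)
    y = cohort.values.loc[gene].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")

    pooled = np.concatenate([x, y])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty_like(pooled)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    while i < sorted_vals.size:
        j = i
        while j + 1 < sorted_vals.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum_x = float(ranks[: x.size].sum())
    u = rank_sum_x - x.size * (x.size + 1) / 2.0
    superiority = u / (x.size * y.size)

    return {
        "gene": gene,
        "n_study": int(x.size),
        "n_cohort": int(y.size),
        "study_median": float(np.median(x)),
        "cohort_median": float(np.median(y)),
        "superiority": float(superiority),
    }


# --- wide-TSV round trip -----------------------------------------------------


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Wide genes x samples TSV with a leading ``#unit=<unit>`` line."""
    with open(path, "w") as fh:
        fh.write(f"#unit={matrix.unit}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene")


def read_expression_tsv(path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#unit="):
            raise ValueError("expression TSV must begin with a '#unit=' line")
        unit = first.removeprefix("#unit=")
        values = pd.read_csv(fh, sep="\t", index_col="gene")
    return ExpressionMatrix(values=values, unit=unit)
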