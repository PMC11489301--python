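"""Per-case integration and cohort-level reporting.

Each case is resolved to a single interpretation by a fixed evidence
hierarchy: a caller-reported fusion involving the gene of interest is
classified by geometry and reading frame; when no such call exists, the
per-exon coverage of the gene is examined for a truncation changepoint; a
case with neither line of evidence is flagged rather than silently passed.
Methylation class and integrated diagnosis are input metadata and are only
tabulated, never computed.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import pandas as pd

from .coverage_truncation import ExonCoverageProfile, detect_truncation
from .fusion_classify import (
    FusionCall,
    Productivity,
    classify_productivity,
    intergenic_label,
    interpretation_label,
    select_primary_call,
)
from .gene_models import GeneModel

__all__ = ["CaseRecord", "CohortSummary", "interpret_case", "summarize_cohort"]

NO_ALTERATION = "no {goi} alteration detected"
INSUFFICIENT = "insufficient evidence"


@dataclass(frozen=True)
class CaseRecord:
    """One case's integrated result (metadata fields are pass-through)."""

    case_id: str
    age: float
    sex: str
    location: str
    methylation_class: str
    rna_result: str
    interpretation: str
    integrated_diagnosis: str
    goi: str
    productivity: str
    warnings: tuple[str, ...] = ()


@dataclass
class CohortSummary:
    n_cases: int
    age_median: float
    age_min: float
    age_max: float
    n_male: int
    n_female: int
    male_female_ratio: float
    counts_by_methylation_class: dict
    counts_by_diagnosis: dict
    counts_by_interpretation: dict
    n_goi_productive: dict
    n_goi_nonproductive: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def interpret_case(
    metadata: Mapping,
    fusion_calls: Sequence[FusionCall],
    coverage: ExonCoverageProfile | None,
    goi: str,
    models: Mapping[str, GeneModel],
    cytobands: Mapping[str, list] | None = None,
    min_fold: float = 10.0,
    max_post_frac: float = 0.1,
) -> CaseRecord:
    """Resolve one case to a Table-1-style record.

    ``metadata`` must carry case_id, age, sex, location, methylation_class
    and integrated_diagnosis.  The primary fusion call (most split reads,
    ties to the lowest breakpoint) wins over coverage evidence; coverage is
    consulted only when the caller saw nothing.
    """
    primary = select_primary_call(list(fusion_calls), goi)
    warn: list[str] = []

    if primary is not None:
        pc = classify_productivity(primary, models)
        warn.extend(pc.warnings)
        interpretation = interpretation_label(pc, goi, primary, models)
        partner = primary.gene2 if primary.gene1 == goi else primary.gene1
        if partner == "." or partner not in models:
            bp = primary.breakpoint2 if primary.gene1 == goi else primary.breakpoint1
            partner = intergenic_label(bp, cytobands)
        # caller-style result string, 5' partner first for genic fusions
        if pc.five_prime_partner is not None and pc.five_prime_partner != goi:
            rna_result = f"{partner}-{goi}"
        elif primary.gene1 != goi and primary.gene2 == goi:
            rna_result = f"{partner}-{goi}"
        else:
            rna_result = f"{goi}-{partner}"
        productivity = pc.productivity.value
    elif coverage is not None:
        tc = detect_truncation(coverage, min_fold=min_fold, max_post_frac=max_post_frac)
        rna_result = "No fusion"
        if tc.truncated:
            interpretation = f"{goi} truncation/non-productive fusion"
            productivity = Productivity.NO_FUSION_DETECTED.value
        else:
            interpretation = NO_ALTERATION.format(goi=goi)
            productivity = Productivity.NO_FUSION_DETECTED.value
            warn.append(f"no fusion call and no coverage truncation for {goi}")
    else:
        rna_result = "No fusion"
        interpretation = INSUFFICIENT
        productivity = Productivity.NO_FUSION_DETECTED.value
        warn.append(f"no fusion call and no coverage table for {goi}")

    return CaseRecord(
        case_id=str(metadata["case_id"]),
        age=float(metadata["age"]),
        sex=str(metadata["sex"]),
        location=str(metadata["location"]),
        methylation_class=str(metadata["methylation_class"]),
        rna_result=rna_result,
        interpretation=interpretation,
        integrated_diagnosis=str(metadata["integrated_diagnosis"]),
        goi=goi,
        productivity=productivity,
        warnings=tuple(warn),
    )


def _median_midpoint(values: list[float]) -> float:
    """Median with the midpoint-of-middle-two convention for even n."""
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def summarize_cohort(records: Sequence[CaseRecord]) -> CohortSummary:
    """Demographic and interpretation tallies over the case records."""
    if not records:
        raise ValueError("no case records to summarize")
    ages = [r.age for r in records]
    n_male = sum(r.sex == "M" for r in records)
    n_female = sum(r.sex == "F" for r in records)
    if n_female == 0:
        warnings.warn("no female cases: male/female ratio reported as inf")
        ratio = math.inf
    else:
        ratio = n_male / n_female

    productive: Counter = Counter()
    nonproductive: Counter = Counter()
    for r in records:
        if "in-frame fusion" in r.interpretation:
            productive[r.goi] += 1
        elif "truncation/non-productive" in r.interpretation:
            nonproductive[r.goi] += 1

    return CohortSummary(
        n_cases=len(records),
        age_median=_median_midpoint(ages),
        age_min=min(ages),
        age_max=max(ages),
        n_male=n_male,
        n_female=n_female,
        male_female_ratio=ratio,
        counts_by_methylation_class=dict(Counter(r.methylation_class for r in records)),
        counts_by_diagnosis=dict(Counter(r.integrated_diagnosis for r in records)),
        counts_by_interpretation=dict(Counter(r.interpretation for r in records)),
        n_goi_productive=dict(productive),
        n_goi_nonproductive=dict(nonproductive),
    )


def records_to_frame(records: Sequence[CaseRecord]) -> pd.DataFrame:
    """Table-1-shaped DataFrame (one row per case, stable column order)."""
    rows = []
    for r in records:
        d = asdict(r)
        d["warnings"] = "; ".join(r.warnings)
        rows.append(d)
    return pd.DataFrame(rows)
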