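"""Synthetic inputs with the statistical structure the pipeline assumes.

Two kinds of data come out of this module:

* **Deterministic 14-case fixture bundles** encoding the study cohort:
  per-case metadata, Arriba-style fusion records whose breakpoint geometry
  realizes each case's event class (head-to-tail in-frame, head-to-tail
  out-of-frame, tail-to-tail, intergenic, or no call), and per-exon coverage
  tables with the expression dropoff at the case's breakpoint exon.  The
  genomic coordinates are simplified round numbers on a bundled six-gene
  mini-annotation (strand-correct models for MYB, MYBL1, QKI, MMP16,
  PCDHGA1, KHDRBS3); the tested content is geometry class, not coordinates.

* **Seeded simulators** for fusion calls with ground-truth labels, Poisson
  per-exon coverage with a known truncation exon, and a log-normal
  expression cohort with configurable group shifts.  Every generator is a
  pure function of its config and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage_truncation import ExonCoverageProfile
from .expression_compare import ExpressionMatrix, counts_to_tpm
from .fusion_classify import FusionCall, Productivity
from .gene_models import GeneModel, breakpoint_context, read_gtf

__all__ = [
    "SimulationConfig",
    "mini_annotation_path",
    "load_reference_models",
    "load_cytobands",
    "load_case_metadata",
    "make_case_fixtures",
    "write_case_fixtures",
    "write_fusion_tsv",
    "write_coverage_tsv",
    "simulate_fusion_calls",
    "simulate_coverage",
    "simulate_cohort",
    "GENES_OF_INTEREST",
]

GENES_OF_INTEREST = ("MYB", "MYBL1")
_REFERENCE_GENES = ("MYB", "MYBL1", "QKI", "MMP16", "PCDHGA1", "KHDRBS3")


# --- bundled reference data --------------------------------------------------


def mini_annotation_path() -> Path:
    """Path of the bundled six-gene mini GTF."""
    return Path(resources.files("fusionframe") / "data" / "mini_annotation.gtf")


def load_reference_models() -> dict[str, GeneModel]:
    """Gene models for the six genes of the bundled mini-annotation."""
    return read_gtf(mini_annotation_path(), _REFERENCE_GENES)


def load_cytobands() -> dict[str, list]:
    """Optional cytoband intervals used only for display labels."""
    path = resources.files("fusionframe") / "data" / "cytobands.json"
    return json.loads(path.read_text())


def load_case_metadata() -> pd.DataFrame:
    """Per-case demographic/diagnostic metadata of the 14-case cohort."""
    path = resources.files("fusionframe") / "data" / "table1_cases.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"case_id": str})


# --- deterministic case fixtures ---------------------------------------------

# (gene1, gene2, bp1, bp2, side1, side2, split_reads) per case; None = no call.
# Breakpoints sit on exon boundaries of the mini models; 3'-partner junctions
# sit on the intronic base just 5' of the first retained exon.
_CASE_FUSIONS: dict[str, tuple | None] = {
    # MYB::QKI head-to-tail, L=2100 (MYB exon 11), D=300 (QKI exons 1-2): in-frame
    "1": ("MYB", "QKI", ("chr6", 110200), ("chr6", 530000), "left", "right", 42),
    "2": ("MYB", "QKI", ("chr6", 110200), ("chr6", 530000), "left", "right", 51),
    # MYB::PCDHGA1 head-to-tail, L=1700 (MYB exon 9), D=200: in-frame
    "3": ("MYB", "PCDHGA1", ("chr6", 90200), ("chr5", 120000), "left", "right", 33),
    "4": ("MYB", "PCDHGA1", ("chr6", 90200), ("chr5", 120000), "left", "right", 27),
    # MYB::QKI with both genes retaining their 5' portions: tail-to-tail
    "5": ("MYB", "QKI", ("chr6", 90200), ("chr6", 550200), "left", "left", 38),
    # MMP16::MYB, both 5' retained: tail-to-tail
    "6": ("MMP16", "MYB", ("chr8", 1060200), ("chr6", 100200), "left", "left", 29),
    # MYB rearranged into intergenic chr6 space (q26 band in the fixture map)
    "7": ("MYB", ".", ("chr6", 150200), ("chr6", 800000), "left", "right", 24),
    "8": ("MYB", ".", ("chr6", 120200), ("chr6", 800000), "left", "right", 19),
    # no caller-visible event; resolved from coverage
    "9": None,
    # MYBL1::MMP16 head-to-tail, L=1700 (MYBL1 exon 9), D=100: out-of-frame
    "10": ("MYBL1", "MMP16", ("chr8", 719801), ("chr8", 1020000), "right", "right", 31),
    "11": ("MYBL1", "MMP16", ("chr8", 719801), ("chr8", 1020000), "right", "right", 26),
    # MYBL1 to intergenic chr8 (q21.3 band) and chr6 (q26 band)
    "12": ("MYBL1", ".", ("chr8", 719801), ("chr8", 3000000), "right", "right", 22),
    "13": ("MYBL1", ".", ("chr8", 719801), ("chr6", 800000), "right", "right", 18),
    # MYBL1::KHDRBS3 head-to-tail, L=1300 (MYBL1 exon 7), D=100: in-frame
    "14": ("MYBL1", "KHDRBS3", ("chr8", 739801), ("chr8", 1990001), "right", "left", 35),
}

#: Last expressed exon of the gene of interest encoded in each case's
#: coverage table; None = expression persists across the whole gene.
_CASE_COVERAGE_DROP: dict[str, int | None] = {
    "1": 11, "2": 11, "3": 9, "4": 9, "5": 9, "6": 10, "7": None, "8": 12,
    "9": 10, "10": 9, "11": 9, "12": 9, "13": 9, "14": 7,
}

_PRE_COUNT = 40  # expressed exons: 40 reads on a 200-nt exon = 200 reads/kb
_POST_PATTERN = (1, 0)  # residual noise downstream of the break (<= 5 reads/kb)


@dataclass(frozen=True)
class CaseBundle:
    """All synthetic inputs for one case."""

    case_id: str
    goi: str
    fusion_calls: tuple[FusionCall, ...]
    coverage: ExonCoverageProfile


def _fixture_coverage(case_id: str, goi: str, model: GeneModel) -> ExonCoverageProfile:
    drop = _CASE_COVERAGE_DROP[case_id]
    lengths = model.exon_lengths()
    counts = []
    for i in range(model.n_exons):
        if drop is None or i < drop:
            counts.append(_PRE_COUNT)
        else:
            counts.append(_POST_PATTERN[(i - drop) % len(_POST_PATTERN)])
    return ExonCoverageProfile(
        case_id=case_id,
        gene_symbol=goi,
        exon_counts=tuple(counts),
        exon_lengths=tuple(lengths),
    )


def make_case_fixtures() -> dict[str, CaseBundle]:
    """The deterministic 14-case bundle set (metadata lives in
    :func:`load_case_metadata`)."""
    models = load_reference_models()
    meta = load_case_metadata().set_index("case_id")
    bundles: dict[str, CaseBundle] = {}
    for case_id, spec in _CASE_FUSIONS.items():
        goi = meta.loc[case_id, "goi"]
        if spec is None:
            calls: tuple[FusionCall, ...] = ()
        else:
            g1, g2, bp1, bp2, s1, s2, sr = spec
            calls = (
                FusionCall(
                    case_id=case_id,
                    gene1=g1,
                    gene2=g2,
                    breakpoint1=bp1,
                    breakpoint2=bp2,
                    retained_side1=s1,
                    retained_side2=s2,
                    split_reads=sr,
                ),
            )
        bundles[case_id] = CaseBundle(
            case_id=case_id,
            goi=goi,
            fusion_calls=calls,
            coverage=_fixture_coverage(case_id, goi, models[goi]),
        )
    return bundles


_ARRIBA_HEADER = (
    "#gene1\tgene2\tstrand1(gene/fusion)\tstrand2(gene/fusion)\tbreakpoint1\t"
    "breakpoint2\tsite1\tsite2\ttype\tdirection1\tdirection2\tsplit_reads1\t"
    "split_reads2\tdiscordant_mates"
)


def _side_to_direction(side: str) -> str:
    return "downstream" if side == "left" else "upstream"


def write_fusion_tsv(calls, path, models: dict[str, GeneModel] | None = None) -> None:
    """Write fusion calls in the Arriba-style TSV dialect the parser reads."""
    models = models or {}
    lines = [_ARRIBA_HEADER]
    for c in calls:
        s1 = models[c.gene1].strand if c.gene1 in models else "."
        s2 = models[c.gene2].strand if c.gene2 in models else "."
        lines.append(
            "\t".join(
                [
                    c.gene1,
                    c.gene2,
                    f"{s1}/{s1}",
                    f"{s2}/{s2}",
                    f"{c.breakpoint1[0]}:{c.breakpoint1[1]}",
                    f"{c.breakpoint2[0]}:{c.breakpoint2[1]}",
                    "splice-site" if c.gene1 in models else "intergenic",
                    "splice-site" if c.gene2 in models else "intergenic",
                    "translocation",
                    _side_to_direction(c.retained_side1),
                    _side_to_direction(c.retained_side2),
                    str(c.split_reads),
                    "0",
                    "3",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_coverage_tsv(profiles, path) -> None:
    """Per-exon count table: case_id, gene, exon_index, exon_length, read_count."""
    rows = []
    for p in profiles:
        for i, (n, ln) in enumerate(zip(p.exon_counts, p.exon_lengths), start=1):
            rows.append((p.case_id, p.gene_symbol, i, ln, n))
    pd.DataFrame(
        rows, columns=["case_id", "gene", "exon_index", "exon_length", "read_count"]
    ).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path) -> list[ExonCoverageProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str})
    profiles = []
    for (case_id, gene), grp in df.groupby(["case_id", "gene"], sort=False):
        grp = grp.sort_values("exon_index")
        profiles.append(
            ExonCoverageProfile(
                case_id=str(case_id),
                gene_symbol=gene,
                exon_counts=tuple(int(x) for x in grp["read_count"]),
                exon_lengths=tuple(int(x) for x in grp["exon_length"]),
            )
        )
    return profiles


def write_case_fixtures(outdir) -> Path:
    """Materialize the fixture bundles as the TSV dialects the CLI reads.

    Layout: ``<outdir>/metadata.tsv``, ``<outdir>/cytobands.json``, and per
    case ``<outdir>/case_<id>/fusions.tsv`` + ``coverage.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models = load_reference_models()
    load_case_metadata().to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    (outdir / "cytobands.json").write_text(json.dumps(load_cytobands(), indent=1))
    for case_id, bundle in make_case_fixtures().items():
        d = outdir / f"case_{case_id}"
        d.mkdir(exist_ok=True)
        write_fusion_tsv(bundle.fusion_calls, d / "fusions.tsv", models)
        write_coverage_tsv([bundle.coverage], d / "coverage.tsv")
    return outdir


# --- seeded simulators -------------------------------------------------------


@dataclass
class SimulationConfig:
    """Knobs of the three seeded generators.

    ``truth_mix`` gives the sampling proportions over productivity classes
    for simulated fusion calls.  Coverage defaults mirror the fixture
    regime: 15 exons, abundant expression at 200 reads/kb collapsing to a
    2 reads/kb background.  The cohort generator draws log-normal TPM-scale
    expression for a 50-gene panel over 1005 reference samples — the scale
    of the archival comparison cohort — plus a study group whose QKI (and
    gene-of-interest) levels are shifted by the configured log2 amounts.
    """

    seed: int = 0
    n_random_fusions: int = 500
    truth_mix: dict = field(
        default_factory=lambda: {
            Productivity.PRODUCTIVE_IN_FRAME: 0.3,
            Productivity.NONPRODUCTIVE_OUT_OF_FRAME: 0.25,
            Productivity.NONPRODUCTIVE_TAIL_TO_TAIL: 0.2,
            Productivity.NONPRODUCTIVE_HEAD_TO_HEAD: 0.1,
            Productivity.NONPRODUCTIVE_INTERGENIC: 0.15,
        }
    )
    # coverage
    n_exons: int = 15
    pre_density: float = 200.0
    post_density: float = 2.0
    exon_length: int = 200
    # cohort
    n_cohort: int = 1005
    n_study: int = 14
    n_filler_genes: int = 47
    log_sigma: float = 0.7
    qki_shift_log2: float = 1.5
    goi_shift_log2: float = 3.0

    def __post_init__(self) -> None:
        total = sum(self.truth_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"truth_mix proportions must sum to 1, got {total}")
        if self.pre_density <= 0 or self.post_density < 0:
            raise ValueError("densities must be positive")


def _coding_offset_to_position(model: GeneModel, offset: int) -> int:
    """Genomic position of the ``offset``-th coding base (transcription order)."""
    if not 1 <= offset <= model.total_cds_length:
        raise ValueError("coding offset outside CDS")
    remaining = offset
    for s, e in model.cds_intervals:
        length = e - s + 1
        if remaining <= length:
            return s + remaining - 1 if model.strand == "+" else e - remaining + 1
        remaining -= length
    raise AssertionError("unreachable")


def _intergenic_position(rng: np.random.Generator) -> tuple[str, int]:
    # gene-free windows of the fixture chromosomes
    windows = [("chr6", 700000, 900000), ("chr8", 2900000, 3100000), ("chr5", 400000, 500000)]
    chrom, lo, hi = windows[rng.integers(len(windows))]
    return chrom, int(rng.integers(lo, hi + 1))


def _random_coding_offset(
    model: GeneModel, rng: np.random.Generator, residue: int | None = None
) -> int:
    """Random in-CDS coding offset, optionally with a fixed value mod 3."""
    total = model.total_cds_length
    if residue is None:
        return int(rng.integers(1, total))
    k_max = (total - 1 - residue) // 3
    offset = residue + 3 * int(rng.integers(0, k_max + 1))
    return offset if offset >= 1 else offset + 3


def simulate_fusion_calls(
    cfg: SimulationConfig, models: dict[str, GeneModel] | None = None
) -> tuple[list[FusionCall], pd.DataFrame]:
    """Fusion calls with per-record ground-truth productivity classes.

    Geometry is constructed to realize the drawn truth: residue-matched or
    mismatched coding offsets for in/out-of-frame head-to-tail events,
    retained-side combinations for tail-to-tail and head-to-head, and
    gene-free breakpoints for intergenic partners.  Returns the calls and a
    truth table (call_id, truth class).
    """
    models = models or load_reference_models()
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.truth_mix)
    probs = np.array([cfg.truth_mix[c] for c in classes])
    partners = {"MYB": ["QKI", "PCDHGA1", "MMP16"], "MYBL1": ["MMP16", "KHDRBS3"]}

    calls: list[FusionCall] = []
    truths: list[tuple[str, str]] = []
    for i in range(cfg.n_random_fusions):
        truth = classes[rng.choice(len(classes), p=probs)]
        goi = GENES_OF_INTEREST[rng.integers(2)]
        m5 = models[goi]
        call_id = f"sim{i:04d}"

        if truth is Productivity.NONPRODUCTIVE_INTERGENIC:
            offset5 = _random_coding_offset(m5, rng)
            bp1 = (m5.chromosome, _coding_offset_to_position(m5, offset5))
            bp2 = _intergenic_position(rng)
            side1 = "left" if m5.strand == "+" else "right"
            side2 = "right" if rng.integers(2) else "left"
            gene2 = "."
        else:
            partner = partners[goi][rng.integers(len(partners[goi]))]
            m3 = models[partner]
            gene2 = partner
            if truth in (
                Productivity.PRODUCTIVE_IN_FRAME,
                Productivity.NONPRODUCTIVE_OUT_OF_FRAME,
            ):
                d = _random_coding_offset(m3, rng)
                if truth is Productivity.PRODUCTIVE_IN_FRAME:
                    residue = d % 3
                else:
                    residue = (d + (1 if rng.integers(2) else 2)) % 3
                offset5 = _random_coding_offset(m5, rng, residue=residue)
                bp1 = (m5.chromosome, _coding_offset_to_position(m5, offset5))
                bp2 = (m3.chromosome, _coding_offset_to_position(m3, d))
                side1 = "left" if m5.strand == "+" else "right"  # 5' retained
                side2 = "right" if m3.strand == "+" else "left"  # 3' retained
            else:
                offset5 = _random_coding_offset(m5, rng)
                d = _random_coding_offset(m3, rng)
                bp1 = (m5.chromosome, _coding_offset_to_position(m5, offset5))
                bp2 = (m3.chromosome, _coding_offset_to_position(m3, d))
                if truth is Productivity.NONPRODUCTIVE_TAIL_TO_TAIL:
                    side1 = "left" if m5.strand == "+" else "right"
                    side2 = "left" if m3.strand == "+" else "right"
                else:  # head-to-head: both 3' retained
                    side1 = "right" if m5.strand == "+" else "left"
                    side2 = "right" if m3.strand == "+" else "left"

        call = FusionCall(
            case_id=call_id,
            gene1=goi,
            gene2=gene2,
            breakpoint1=bp1,
            breakpoint2=bp2,
            retained_side1=side1,
            retained_side2=side2,
            split_reads=int(rng.integers(3, 80)),
        )
        if rng.integers(2):  # partner bookkeeping order is arbitrary
            call = call.swapped()
        calls.append(call)
        truths.append((call_id, truth.value))

    truth_table = pd.DataFrame(truths, columns=["case_id", "truth"])
    return calls, truth_table


def simulate_coverage(
    cfg: SimulationConfig,
    truncation_exon: int | None,
    case_id: str = "sim",
    gene_symbol: str = "MYB",
    rng: np.random.Generator | None = None,
) -> ExonCoverageProfile:
    """Poisson per-exon counts with an optional truncation after exon ``k``."""
    if truncation_exon is not None and not 1 <= truncation_exon < cfg.n_exons:
        raise ValueError("truncation_exon must lie in [1, n_exons-1]")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    lengths = np.full(cfg.n_exons, cfg.exon_length)
    dens = np.full(cfg.n_exons, cfg.pre_density, dtype=float)
    if truncation_exon is not None:
        dens[truncation_exon:] = cfg.post_density
    counts = rng.poisson(lengths / 1000.0 * dens)
    return ExonCoverageProfile(
        case_id=case_id,
        gene_symbol=gene_symbol,
        exon_counts=tuple(int(c) for c in counts),
        exon_lengths=tuple(int(x) for x in lengths),
    )


def simulate_cohort(
    cfg: SimulationConfig,
    qki_shift_log2: float | None = None,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Log-normal expression cohort plus a shifted study group, as TPM.

    Counts for a small gene panel (the six reference genes + filler genes)
    are drawn per sample from log-normal expression levels and converted to
    TPM; study-group samples receive ``qki_shift_log2`` on QKI and
    ``goi_shift_log2`` on MYB/MYBL1.  Returns the TPM matrix and a Series of
    group labels ("study"/"cohort") indexed by sample.
    """
    rng = np.random.default_rng(cfg.seed)
    shift = cfg.qki_shift_log2 if qki_shift_log2 is None else qki_shift_log2
    models = load_reference_models()

    genes = list(_REFERENCE_GENES) + [f"GENE{i:03d}" for i in range(cfg.n_filler_genes)]
    lengths = {g: sum(models[g].exon_lengths()) for g in _REFERENCE_GENES}
    filler_lengths = rng.integers(500, 5000, size=cfg.n_filler_genes)
    lengths.update(
        {f"GENE{i:03d}": int(l) for i, l in enumerate(filler_lengths)}
    )

    base_log = {"MYB": np.log(30.0), "MYBL1": np.log(20.0), "QKI": np.log(100.0),
                "MMP16": np.log(15.0), "PCDHGA1": np.log(10.0), "KHDRBS3": np.log(25.0)}
    filler_log = rng.normal(np.log(50.0), 1.0, size=cfg.n_filler_genes)
    mu = np.concatenate([[base_log[g] for g in _REFERENCE_GENES], filler_log])

    n_total = cfg.n_cohort + cfg.n_study
    log_expr = rng.normal(mu[:, None], cfg.log_sigma, size=(len(genes), n_total))
    labels = np.array(["cohort"] * cfg.n_cohort + ["study"] * cfg.n_study)
    study = labels == "study"
    gi = {g: i for i, g in enumerate(genes)}
    log_expr[gi["QKI"], study] += shift * np.log(2.0)
    for goi in GENES_OF_INTEREST:
        log_expr[gi[goi], study] += cfg.goi_shift_log2 * np.log(2.0)

    # expression level -> expected read count ~ level * length_kb * depth
    length_kb = np.array([lengths[g] / 1000.0 for g in genes])
    lam = np.exp(log_expr) * length_kb[:, None] * 2.0
    counts = rng.poisson(lam)

    samples = [f"REF{i:04d}" for i in range(cfg.n_cohort)] + [
        f"CASE{i + 1}" for i in range(cfg.n_study)
    ]
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    tpm = counts_to_tpm(counts_df, lengths)
    return tpm, pd.Series(labels, index=samples, name="group")
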