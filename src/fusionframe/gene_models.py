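"""Gene structures and coding-phase arithmetic at genomic breakpoints.

All coordinates are 1-based inclusive (GTF convention), here and in every
record schema of this package.  Exons and CDS intervals are stored in
transcription order: ascending genomic position for ``+`` strand genes,
descending for ``-`` strand genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GeneModel",
    "BreakpointContext",
    "GtfParseError",
    "GeneNotFoundError",
    "DEFAULT_CLUSTER_ALIASES",
    "read_gtf",
    "breakpoint_context",
]

#: Display-family aliases for clustered gene families (protocadherin-gamma
#: members are conventionally reported under the cluster name).
DEFAULT_CLUSTER_ALIASES: Mapping[str, str] = {"PCDHGA1": "PCDHG"}


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message carries the line number."""


class GeneNotFoundError(KeyError):
    """Requested gene symbols absent from the annotation."""

    def __init__(self, missing: Iterable[str]):
        self.missing = sorted(missing)
        super().__init__(f"gene(s) not found in GTF: {', '.join(self.missing)}")


@dataclass(frozen=True)
class GeneModel:
    """One canonical transcript model of a gene.

    Parameters
    ----------
    gene_symbol : str
        HGNC-style symbol.
    chromosome : str
        Chromosome name as spelled in the annotation.
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (int, int)
        1-based inclusive genomic intervals in transcription order
        (exon 1 first; descending genomic coordinates on ``-`` strand).
    cds_intervals : tuple of (int, int)
        CDS genomic intervals, transcription order, each contained in an exon.
    cluster_alias : str or None
        Optional display family (e.g. PCDHGA1 -> "PCDHG").
    """

    gene_symbol: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_intervals: tuple[tuple[int, int], ...] = ()
    cluster_alias: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.exons + self.cds_intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
        # exons must not overlap
        by_pos = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(by_pos, by_pos[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        for cs, ce in self.cds_intervals:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise ValueError(f"CDS interval ({cs}, {ce}) not contained in any exon")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def gene_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def gene_end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def total_cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def cds_length_multiple_of_three(self) -> bool:
        """False flags a partial/truncated model; partial models are allowed."""
        return self.total_cds_length % 3 == 0

    @property
    def display_name(self) -> str:
        return self.cluster_alias or self.gene_symbol

    def exon_lengths(self) -> list[int]:
        return [e - s + 1 for s, e in self.exons]

    def exon_index_at(self, position: int) -> int | None:
        """1-based exon number (transcription order) containing ``position``."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= position <= e:
                return i
        return None

    def junction_exon(self, position: int) -> int | None:
        """Exon adjacent to a breakpoint: the containing exon, or for an
        intronic position the last exon transcriptionally upstream of it."""
        idx = self.exon_index_at(position)
        if idx is not None:
            return idx
        if not (self.gene_start <= position <= self.gene_end):
            return None
        best = None
        for i, (s, e) in enumerate(self.exons, start=1):
            if self.strand == "+":
                if e < position:
                    best = i
            else:
                if s > position:
                    best = i
        return best


@dataclass(frozen=True)
class BreakpointContext:
    """Coding context of a genomic position relative to one gene model.

    ``coding_nt_upstream`` is the number of coding nucleotides of this gene
    transcriptionally 5' of the breakpoint, with the breakpoint base itself
    counted as retained on the 5' side.  This is the quantity ``L`` for a
    5'-retained fusion partner and ``D`` (discarded coding prefix) for a
    3'-retained partner in the reading-frame rule.
    """

    gene_symbol: str
    position: int
    within_gene: bool
    within_cds: bool
    coding_nt_upstream: int
    junction_exon: int | None


def breakpoint_context(model: GeneModel, position: int) -> BreakpointContext:
    """Compute the coding context of ``position`` for ``model``.

    The position may fall anywhere, including outside the gene; positions
    transcriptionally upstream of all CDS yield ``coding_nt_upstream = 0``.
    """
    within_gene = model.gene_start <= position <= model.gene_end
    within_cds = any(s <= position <= e for s, e in model.cds_intervals)

    coding = 0
    for s, e in model.cds_intervals:
        if model.strand == "+":
            if e <= position:
                coding += e - s + 1
            elif s <= position:
                coding += position - s + 1
        else:
            if s >= position:
                coding += e - s + 1
            elif e >= position:
                coding += e - position + 1
    return BreakpointContext(
        gene_symbol=model.gene_symbol,
        position=position,
        within_gene=within_gene,
        within_cds=within_cds,
        coding_nt_upstream=coding,
        junction_exon=model.junction_exon(position) if within_gene else None,
    )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(
    path,
    gene_symbols: Iterable[str],
    cluster_aliases: Mapping[str, str] = DEFAULT_CLUSTER_ALIASES,
) -> dict[str, GeneModel]:
    """Load one canonical :class:`GeneModel` per requested gene from a GTF.

    The canonical transcript is the one with the longest total CDS; ties are
    broken by the lexicographically lowest transcript id.  Exons are returned
    in transcription order.

    Raises
    ------
    GeneNotFoundError
        If any requested symbol has no transcript in the file.
    GtfParseError
        On a malformed line, with the offending line number.
    """
    wanted = set(gene_symbols)
    # gene -> transcript_id -> {"strand","chrom","exons":[],"cds":[]}
    transcripts: dict[str, dict[str, dict]] = {g: {} for g in wanted}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields[:9]
            if feature not in {"exon", "CDS"}:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            attrs = _parse_attributes(attr)
            gene = attrs.get("gene_name") or attrs.get("gene_id")
            if gene not in wanted:
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            rec = transcripts[gene].setdefault(
                tid, {"chrom": chrom, "strand": strand, "exons": [], "cds": []}
            )
            rec["exons" if feature == "exon" else "cds"].append((start, end))

    missing = {g for g in wanted if not transcripts[g]}
    if missing:
        raise GeneNotFoundError(missing)

    models: dict[str, GeneModel] = {}
    for gene, tids in transcripts.items():
        # canonical = longest CDS, tie -> lowest transcript id
        best_tid = min(
            tids, key=lambda t: (-sum(e - s + 1 for s, e in tids[t]["cds"]), t)
        )
        rec = tids[best_tid]
        reverse = rec["strand"] == "-"
        exons = tuple(sorted(rec["exons"], reverse=reverse))
        cds = tuple(sorted(rec["cds"], reverse=reverse))
        models[gene] = GeneModel(
            gene_symbol=gene,
            chromosome=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            cds_intervals=cds,
            cluster_alias=cluster_aliases.get(gene),
        )
    return models
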