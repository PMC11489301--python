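"""Orientation and reading-frame classification of fusion-caller records.

A rearrangement joining two genes is only capable of expressing a chimeric
protein when it is *head-to-tail* (the 5' portion of one gene joined to the
3' portion of the other) **and** the junction preserves the reading frame:
with ``L`` coding nucleotides retained from the 5' partner and ``D`` coding
nucleotides discarded from the start of the 3' partner, the chimera is
in-frame iff ``(L - D) % 3 == 0``.  Tail-to-tail junctions (both genes
retaining their 5' portions, transcribed convergently) and head-to-head
junctions cannot form a single-sense chimeric ORF and are non-productive by
geometry alone, as are rearrangements into intergenic space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .gene_models import GeneModel, breakpoint_context

__all__ = [
    "FusionCall",
    "Orientation",
    "Frame",
    "Productivity",
    "ProductivityCall",
    "FusionFileError",
    "parse_fusion_records",
    "retained_orientation",
    "classify_orientation",
    "frame_compatibility",
    "classify_productivity",
    "interpretation_label",
    "select_primary_call",
    "intergenic_label",
]

logger = logging.getLogger(__name__)


class FusionFileError(ValueError):
    """Schema or row-level error in a fusion-call file."""


class Orientation(str, Enum):
    HEAD_TO_TAIL = "head_to_tail"
    TAIL_TO_TAIL = "tail_to_tail"
    HEAD_TO_HEAD = "head_to_head"
    INTERGENIC = "intergenic"
    NOT_APPLICABLE = "not_applicable"


class Frame(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    NOT_APPLICABLE = "not_applicable"


class Productivity(str, Enum):
    PRODUCTIVE_IN_FRAME = "PRODUCTIVE_IN_FRAME"
    NONPRODUCTIVE_OUT_OF_FRAME = "NONPRODUCTIVE_OUT_OF_FRAME"
    NONPRODUCTIVE_TAIL_TO_TAIL = "NONPRODUCTIVE_TAIL_TO_TAIL"
    NONPRODUCTIVE_HEAD_TO_HEAD = "NONPRODUCTIVE_HEAD_TO_HEAD"
    NONPRODUCTIVE_INTERGENIC = "NONPRODUCTIVE_INTERGENIC"
    NO_FUSION_DETECTED = "NO_FUSION_DETECTED"


@dataclass(frozen=True)
class FusionCall:
    """One fusion-caller record (coordinates 1-based inclusive).

    ``retained_side1``/``retained_side2`` give the genomic side (``"left"``
    or ``"right"``) of each breakpoint retained in the rearranged allele.
    ``gene1``/``gene2`` may be ``"."`` or an intergenic locus label.
    """

    case_id: str
    gene1: str
    gene2: str
    breakpoint1: tuple[str, int]
    breakpoint2: tuple[str, int]
    retained_side1: str
    retained_side2: str
    split_reads: int = 0
    caller_frame_annotation: str | None = None

    def __post_init__(self) -> None:
        if self.split_reads < 0:
            raise ValueError("split_reads must be >= 0")
        for side in (self.retained_side1, self.retained_side2):
            if side not in {"left", "right"}:
                raise ValueError(f"retained_side must be 'left'/'right', got {side!r}")

    def swapped(self) -> "FusionCall":
        """The same event with partner 1/2 bookkeeping exchanged."""
        return FusionCall(
            case_id=self.case_id,
            gene1=self.gene2,
            gene2=self.gene1,
            breakpoint1=self.breakpoint2,
            breakpoint2=self.breakpoint1,
            retained_side1=self.retained_side2,
            retained_side2=self.retained_side1,
            split_reads=self.split_reads,
            caller_frame_annotation=self.caller_frame_annotation,
        )


@dataclass(frozen=True)
class ProductivityCall:
    """Orientation class + frame verdict + Table-1-style productivity."""

    orientation: Orientation
    frame: Frame
    productivity: Productivity
    five_prime_partner: str | None = None
    interpretation_label: str = ""
    warnings: tuple[str, ...] = ()


# --- parsing -----------------------------------------------------------------

_REQUIRED_COLUMNS = (
    "gene1",
    "gene2",
    "breakpoint1",
    "breakpoint2",
    "direction1",
    "direction2",
)


def _direction_to_retained_side(direction: str) -> str:
    """Normalize caller direction vocabulary to a retained genomic side.

    ``downstream`` means the retained segment extends to the left of
    (through) the breakpoint; ``upstream`` means it extends to the right.
    This is the single place the caller vocabulary is interpreted.
    """
    d = direction.strip().lower()
    if d == "downstream":
        return "left"
    if d == "upstream":
        return "right"
    raise FusionFileError(f"unrecognized direction value {direction!r}")


def _parse_breakpoint(text: str) -> tuple[str, int]:
    chrom, _, pos = text.strip().partition(":")
    if not chrom or not pos:
        raise ValueError(f"malformed breakpoint {text!r}")
    return chrom, int(pos)


def parse_fusion_records(path, case_id: str | None = None) -> list[FusionCall]:
    """Parse an Arriba-style tab-separated fusion file.

    The header must name at least ``gene1 gene2 breakpoint1 breakpoint2
    direction1 direction2`` plus either ``split_reads`` or the pair
    ``split_reads1``/``split_reads2`` (summed).  A leading ``#`` on the
    header's first column name is tolerated.  ``case_id``, if not given,
    is taken from a ``case_id`` column when present, else "".
    """
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise FusionFileError("empty fusion file: no header")
        header = [h.lstrip("#") for h in header_line.rstrip("\n").split("\t")]
        col = {name: i for i, name in enumerate(header)}
        for name in _REQUIRED_COLUMNS:
            if name not in col:
                raise FusionFileError(f"missing mandatory column: {name}")
        has_sr = "split_reads" in col
        if not has_sr and not ("split_reads1" in col and "split_reads2" in col):
            raise FusionFileError("missing mandatory column: split_reads")

        calls: list[FusionCall] = []
        for rowno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                bp1 = _parse_breakpoint(fields[col["breakpoint1"]])
                bp2 = _parse_breakpoint(fields[col["breakpoint2"]])
                if has_sr:
                    split_reads = int(fields[col["split_reads"]])
                else:
                    split_reads = int(fields[col["split_reads1"]]) + int(
                        fields[col["split_reads2"]]
                    )
                calls.append(
                    FusionCall(
                        case_id=case_id
                        or (fields[col["case_id"]] if "case_id" in col else ""),
                        gene1=fields[col["gene1"]],
                        gene2=fields[col["gene2"]],
                        breakpoint1=bp1,
                        breakpoint2=bp2,
                        retained_side1=_direction_to_retained_side(
                            fields[col["direction1"]]
                        ),
                        retained_side2=_direction_to_retained_side(
                            fields[col["direction2"]]
                        ),
                        split_reads=split_reads,
                        caller_frame_annotation=(
                            fields[col["reading_frame"]] if "reading_frame" in col else None
                        ),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FusionFileError(f"row {rowno}: {exc}") from exc
    return calls


# --- classification ----------------------------------------------------------


def _is_genic(gene: str, bp: tuple[str, int], models: Mapping[str, GeneModel]) -> bool:
    model = models.get(gene)
    if model is None:
        return False
    chrom, pos = bp
    return model.chromosome == chrom and model.gene_start <= pos <= model.gene_end


def _retained_side_one(
    gene: str, bp: tuple[str, int], retained_side: str, models: Mapping[str, GeneModel]
) -> str:
    if not _is_genic(gene, bp, models):
        return "intergenic"
    strand = models[gene].strand
    if (retained_side == "left") == (strand == "+"):
        return "five_prime"
    return "three_prime"


def retained_orientation(
    call: FusionCall, models: Mapping[str, GeneModel]
) -> tuple[str, str]:
    """Retained transcript side for each breakpoint.

    ``five_prime`` iff the retained genomic side is left on a ``+`` strand
    gene or right on a ``-`` strand gene; ``intergenic`` when the breakpoint
    lies in no known model.
    """
    return (
        _retained_side_one(call.gene1, call.breakpoint1, call.retained_side1, models),
        _retained_side_one(call.gene2, call.breakpoint2, call.retained_side2, models),
    )


def classify_orientation(
    call: FusionCall, models: Mapping[str, GeneModel]
) -> Orientation:
    side1, side2 = retained_orientation(call, models)
    if "intergenic" in (side1, side2):
        return Orientation.INTERGENIC
    if side1 == side2 == "five_prime":
        return Orientation.TAIL_TO_TAIL
    if side1 == side2 == "three_prime":
        return Orientation.HEAD_TO_HEAD
    return Orientation.HEAD_TO_TAIL


def frame_compatibility(
    call: FusionCall, models: Mapping[str, GeneModel]
) -> tuple[Frame, tuple[str, ...]]:
    """Reading-frame verdict for a head-to-tail call.

    Returns ``(frame, warnings)``.  ``not_applicable`` (never an exception)
    when the call is not head-to-tail or when either junction lies outside
    CDS so that L or D is undefined — e.g. a 5'-UTR breakpoint on the 5'
    partner (promoter retained but no coding prefix), flagged with a warning
    rather than silently forced to out-of-frame.
    """
    if classify_orientation(call, models) is not Orientation.HEAD_TO_TAIL:
        return Frame.NOT_APPLICABLE, ()

    side1, _ = retained_orientation(call, models)
    if side1 == "five_prime":
        five = (call.gene1, call.breakpoint1)
        three = (call.gene2, call.breakpoint2)
    else:
        five = (call.gene2, call.breakpoint2)
        three = (call.gene1, call.breakpoint1)

    ctx5 = breakpoint_context(models[five[0]], five[1][1])
    ctx3 = breakpoint_context(models[three[0]], three[1][1])
    L, D = ctx5.coding_nt_upstream, ctx3.coding_nt_upstream

    warn: list[str] = []
    if L == 0:
        warn.append(
            f"{five[0]} breakpoint upstream of CDS (5'-UTR/promoter junction): "
            "frame undefined"
        )
        return Frame.NOT_APPLICABLE, tuple(warn)
    if D >= models[three[0]].total_cds_length and not ctx3.within_cds:
        warn.append(f"{three[0]} breakpoint downstream of CDS: frame undefined")
        return Frame.NOT_APPLICABLE, tuple(warn)
    return (Frame.IN_FRAME if (L - D) % 3 == 0 else Frame.OUT_OF_FRAME), tuple(warn)


def classify_productivity(
    call: FusionCall, models: Mapping[str, GeneModel]
) -> ProductivityCall:
    """Total classification of one call into a productivity class."""
    orientation = classify_orientation(call, models)
    frame, warn = frame_compatibility(call, models)
    warn = list(warn)

    five_prime_partner: str | None = None
    if orientation is Orientation.HEAD_TO_TAIL:
        side1, _ = retained_orientation(call, models)
        five_prime_partner = call.gene1 if side1 == "five_prime" else call.gene2
        if frame is Frame.IN_FRAME:
            productivity = Productivity.PRODUCTIVE_IN_FRAME
        else:
            # frame not_applicable (UTR junction) is conservatively grouped
            # with non-productive, carrying its warning flag
            productivity = Productivity.NONPRODUCTIVE_OUT_OF_FRAME
    elif orientation is Orientation.TAIL_TO_TAIL:
        productivity = Productivity.NONPRODUCTIVE_TAIL_TO_TAIL
    elif orientation is Orientation.HEAD_TO_HEAD:
        productivity = Productivity.NONPRODUCTIVE_HEAD_TO_HEAD
    else:
        productivity = Productivity.NONPRODUCTIVE_INTERGENIC

    if call.caller_frame_annotation:
        ours = {
            Frame.IN_FRAME: "in-frame",
            Frame.OUT_OF_FRAME: "out-of-frame",
        }.get(frame)
        theirs = call.caller_frame_annotation.strip().lower()
        if ours is not None and theirs in {"in-frame", "out-of-frame"} and theirs != ours:
            msg = (
                f"caller frame annotation {theirs!r} discordant with geometry "
                f"verdict {ours!r}; geometry verdict retained"
            )
            warn.append(msg)
            logger.warning("%s: %s", call.case_id, msg)

    return ProductivityCall(
        orientation=orientation,
        frame=frame,
        productivity=productivity,
        five_prime_partner=five_prime_partner,
        interpretation_label="",
        warnings=tuple(warn),
    )


def intergenic_label(
    bp: tuple[str, int], cytobands: Mapping[str, list] | None = None
) -> str:
    """Locus label for an intergenic partner: ``Chr<N>:<cytoband>`` when a
    cytoband map covers the position, else ``chr<N>:<pos>``."""
    chrom, pos = bp
    if cytobands:
        for start, end, name in cytobands.get(chrom, []):
            if start <= pos <= end:
                return f"{chrom[0].upper()}{chrom[1:]}:{name}"
    return f"{chrom}:{pos}"


def interpretation_label(
    pc: ProductivityCall,
    gene_of_interest: str,
    call: FusionCall | None,
    models: Mapping[str, GeneModel],
) -> str:
    """Table-1-style interpretation string for a classified call.

    Productive calls read ``"<GOI> in-frame fusion (to <partner>)"`` with the
    partner's cluster alias when one is set; every non-productive class reads
    ``"<GOI> truncation/non-productive fusion"``.
    """
    if pc.productivity is Productivity.NO_FUSION_DETECTED or call is None:
        return f"{gene_of_interest} truncation/non-productive fusion"
    if gene_of_interest not in (call.gene1, call.gene2):
        raise ValueError(
            f"gene of interest {gene_of_interest} is not a partner of this call "
            f"({call.gene1}, {call.gene2})"
        )
    if pc.productivity is Productivity.PRODUCTIVE_IN_FRAME:
        partner = call.gene2 if call.gene1 == gene_of_interest else call.gene1
        model = models.get(partner)
        partner_name = model.display_name if model else partner
        return f"{gene_of_interest} in-frame fusion (to {partner_name})"
    return f"{gene_of_interest} truncation/non-productive fusion"


def select_primary_call(
    calls: list[FusionCall], gene_of_interest: str
) -> FusionCall | None:
    """The call involving the gene of interest with most split reads; ties
    broken by lowest breakpoint coordinate."""
    involving = [c for c in calls if gene_of_interest in (c.gene1, c.gene2)]
    if not involving:
        return None
    return min(
        involving,
        key=lambda c: (-c.split_reads, min(c.breakpoint1[1], c.breakpoint2[1])),
    )
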