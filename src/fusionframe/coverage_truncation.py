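"""Per-exon coverage changepoint detection for cryptic truncations.

When a rearrangement disrupts a gene without producing a caller-visible
fusion transcript, the RNA coverage track still betrays it: read depth is
abundant over the exons upstream of the genomic break and collapses to
background noise downstream.  This module formalizes that visual read-out as
a single-changepoint segmentation of length-normalized per-exon densities,
scored with a two-segment Gaussian log-likelihood on log1p(density) and
gated by a fold-drop and a background criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExonCoverageProfile",
    "TruncationCall",
    "exon_density",
    "detect_truncation",
    "truncation_consistency",
    "last_expressed_exon",
]

_EPS = 1e-9


@dataclass(frozen=True)
class ExonCoverageProfile:
    """Reads overlapping each exon of one gene in one case.

    ``exon_counts`` and ``exon_lengths`` are in transcription order (exon 1
    first).  ``background_reference`` is an optional expected noise-level
    density (reads/kb), e.g. the median per-kb density of control genes in
    the same library.
    """

    case_id: str
    gene_symbol: str
    exon_counts: tuple[int, ...]
    exon_lengths: tuple[int, ...]
    background_reference: float | None = None

    def __post_init__(self) -> None:
        if len(self.exon_counts) != len(self.exon_lengths):
            raise ValueError("counts and lengths must have the same length")
        if any(c < 0 for c in self.exon_counts):
            raise ValueError("counts must be >= 0")

    @property
    def n_exons(self) -> int:
        return len(self.exon_counts)


@dataclass(frozen=True)
class TruncationCall:
    """Result of single-changepoint truncation detection.

    ``last_expressed_exon`` is the 1-based index of the final exon of the
    expressed (upstream) segment when ``truncated`` is true, else None.
    ``statistic`` is the two-segment minus one-segment log-likelihood at the
    chosen changepoint.
    """

    truncated: bool
    last_expressed_exon: int | None
    pre_mean_density: float
    post_mean_density: float
    fold_drop: float
    statistic: float


def exon_density(profile: ExonCoverageProfile) -> np.ndarray:
    """Per-exon read density in reads per kilobase."""
    lengths = np.asarray(profile.exon_lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("exon lengths must be > 0")
    counts = np.asarray(profile.exon_counts, dtype=float)
    return 1000.0 * counts / lengths


def _rss(x: np.ndarray) -> float:
    """Residual sum of squares around the segment mean."""
    return float(np.sum((x - x.mean()) ** 2))


def _loglik_gain(y: np.ndarray, k: int) -> float:
    """Two-segment minus one-segment Gaussian log-likelihood at split ``k``.

    Both models share a single (profiled-out) variance, so the gain reduces
    to ``n/2 * log(RSS_1 / RSS_2)``; a shared variance keeps length-one
    segments from degenerating to infinite likelihood.
    """
    n = y.size
    rss1 = max(_rss(y), _EPS)
    rss2 = max(_rss(y[:k]) + _rss(y[k:]), _EPS)
    return 0.5 * n * np.log(rss1 / rss2)


def detect_truncation(
    profile: ExonCoverageProfile,
    min_fold: float = 10.0,
    max_post_frac: float = 0.1,
) -> TruncationCall:
    """Locate the exon after which expression drops to background.

    Every candidate changepoint ``k`` in ``[1, n-1]`` splits the log1p
    density vector into ``[1..k]`` and ``[k+1..n]``; each split is scored by
    the gain of the two-segment Gaussian log-likelihood over the one-segment
    fit, and the argmax (smallest ``k`` on ties) is the candidate breakpoint.
    The call is reported as a truncation only if the drop is real:

    * ``fold_drop = pre_mean_density / max(post_mean_density, eps) >= min_fold``
    * ``post_mean_density <= max(background_reference, max_post_frac * pre)``
      (the background term only when a reference is supplied).

    A flat or rising profile fails the gates and returns ``truncated=False``.
    """
    if profile.n_exons < 3:
        raise ValueError("changepoint detection needs at least 3 exons")
    dens = exon_density(profile)
    if not np.any(dens > 0):
        warnings.warn(f"{profile.case_id}/{profile.gene_symbol}: no expression")
        return TruncationCall(False, None, 0.0, 0.0, 0.0, 0.0)

    y = np.log1p(dens)
    n = y.size
    best_k, best_stat = 1, -np.inf
    for k in range(1, n):
        stat = _loglik_gain(y, k)
        if stat > best_stat:  # strict: ties keep the smallest k
            best_k, best_stat = k, stat

    pre = float(np.mean(dens[:best_k]))
    post = float(np.mean(dens[best_k:]))
    fold = pre / max(post, _EPS)

    post_cap = max_post_frac * pre
    if profile.background_reference is not None:
        post_cap = max(profile.background_reference, post_cap)

    truncated = fold >= min_fold and post <= post_cap
    return TruncationCall(
        truncated=truncated,
        last_expressed_exon=best_k if truncated else None,
        pre_mean_density=pre,
        post_mean_density=post,
        fold_drop=fold,
        statistic=float(best_stat),
    )


def last_expressed_exon(
    profile: ExonCoverageProfile,
    min_fold: float = 10.0,
    max_post_frac: float = 0.1,
) -> int | None:
    """Final expressed exon: the changepoint when a truncation is detected,
    the last exon when expression persists across the whole gene, None when
    the gene is not expressed at all."""
    tc = detect_truncation(profile, min_fold=min_fold, max_post_frac=max_post_frac)
    if tc.truncated:
        return tc.last_expressed_exon
    if np.any(exon_density(profile) > 0):
        return profile.n_exons
    return None


def truncation_consistency(
    tc: TruncationCall,
    fusion_breakpoint_exon: int | None,
    n_exons: int | None = None,
) -> str:
    """Agreement between the coverage changepoint and a fusion breakpoint.

    ``consistent`` when the last expressed exon is within one exon of the
    fusion junction exon, ``no_fusion`` when no fusion exon is supplied.
    When no truncation was detected but the gene is expressed, the last
    expressed exon is the final exon (``n_exons``, if given) — the pattern
    of a breakpoint at or beyond the gene's 3' end.
    """
    if fusion_breakpoint_exon is None:
        return "no_fusion"
    last = tc.last_expressed_exon
    if last is None and not tc.truncated and tc.pre_mean_density > 0:
        last = n_exons
    if last is None:
        return "inconsistent"
    return "consistent" if abs(last - fusion_breakpoint_exon) <= 1 else "inconsistent"
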