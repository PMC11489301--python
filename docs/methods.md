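# Methods

## Problem setting

RNA-seq fusion callers report candidate rearrangements as gene pairs with
two breakpoints and, per breakpoint, the genomic side retained in the
rearranged allele.  For *MYB*/*MYBL1*-altered gliomas the diagnostic
question is not merely *is there a rearrangement* but *can it express a
chimeric protein*.  `fusionframe` answers that from three lines of
evidence: breakpoint geometry, reading-frame arithmetic, and — for
caller-invisible events — the per-exon coverage profile of the gene itself.
Expression of the genes of interest is additionally placed in the context
of a large reference cohort.

## Gene models and coordinates

All coordinates are 1-based inclusive (GTF convention).  A gene is
represented by one canonical transcript — the one with the longest total
CDS, ties broken by the lexicographically lowest transcript id — with exons
and CDS intervals stored in transcription order (descending genomic
coordinates on the − strand).  Transcript choice matters only for exon
numbering; since no single authoritative numbering exists for these genes,
the bundled annotation fixes one model per gene and all exon indices in
this package refer to it.

`coding_nt_upstream(position)` counts the coding nucleotides of a gene
transcriptionally 5′ of a breakpoint, with the breakpoint base itself
counted as retained on the 5′ side — consistent with callers reporting the
last retained base of a segment.  It is monotone along transcription order
and reaches the total CDS length at the transcriptional end of the gene
(property-tested against brute-force base enumeration).

The bundled mini-annotation contains six strand-correct models — MYB (+,
15 exons), QKI (+), PCDHGA1 (+, cluster alias PCDHG), MYBL1 (−), MMP16 (+),
KHDRBS3 (−) — on simplified round-number coordinates.  Exon counts and
strands are realistic; base positions are synthetic.  Geometry class, not
coordinates, is the content the fixtures encode.

## Orientation and reading frame

For each breakpoint, the retained transcript side is

    five_prime  iff (retained genomic side = left  and strand = +)
                or  (retained genomic side = right and strand = −)

The caller's `direction1/direction2` vocabulary is normalized in exactly
one parser function: `downstream` ⇒ retained side left (the retained
segment extends through the breakpoint from the left), `upstream` ⇒ right.

Orientation over the pair of retained sides:

| side 1 | side 2 | orientation |
|---|---|---|
| 5′ | 3′ (or 3′/5′) | head-to-tail |
| 5′ | 5′ | tail-to-tail |
| 3′ | 3′ | head-to-head |
| any | no gene model at breakpoint | intergenic |

Only head-to-tail junctions can yield a chimeric ORF.  With `L` the coding
nucleotides retained from the 5′ partner and `D` the coding prefix
discarded from the 3′ partner, the junction is in-frame iff
`(L − D) mod 3 = 0`.  Of the nine (L mod 3, D mod 3) residue pairs exactly
the three diagonal ones are in-frame (enumerated in tests).  A breakpoint
in the 5′ partner's 5′-UTR leaves `L` undefined; the frame verdict is then
`not_applicable` with an explicit warning flag rather than a silent
out-of-frame call, though the productivity class remains non-productive
(no chimeric ORF is demonstrated).  When the caller supplies its own frame
annotation it is compared against the geometry verdict and discordance is
logged; the geometry verdict wins.

When several calls involve the gene of interest, the one with most split
reads is primary (ties: lowest breakpoint coordinate).  Swapping the two
partners' bookkeeping order leaves orientation and productivity unchanged
(property-tested).

## Coverage-changepoint truncation

Input is a per-exon read-count table (counts, not normalized depth).
Counts are length-normalized to reads/kb, transformed with log1p, and every
split `k ∈ [1, n−1]` is scored by the gain of the two-segment Gaussian
log-likelihood over the one-segment fit.  Both models share a single
profiled-out variance, so the gain is `n/2 · log(RSS₁/RSS₂(k))`; sharing
the variance keeps length-one segments from degenerating to infinite
likelihood.  The argmax (smallest `k` on ties) is the candidate breakpoint,
reported as a truncation only when

* `fold_drop = pre_mean / max(post_mean, ε) ≥ min_fold` (default 10), and
* `post_mean ≤ max(background_reference, max_post_frac × pre_mean)`
  (default `max_post_frac` = 0.1; the background reference, when supplied,
  is meant to be the median per-kb density of control genes in the same
  library).

The defaults formalize "abundant expression collapsing to background": a
ten-fold drop to ≤ 10% of the upstream level.  Raising `min_fold` can only
remove truncation calls, never create them (tested).  The estimate is
invariant to scaling all counts by a constant on well-separated profiles;
exact invariance is not guaranteed for marginal drops because log1p is not
scale-equivariant at small densities.  A single changepoint is modeled;
multi-break events are out of scope.  Calibration: at 200 vs 2 reads/kb
over 15 exons (200-nt exons, Poisson noise, truncation exon uniform), the
true exon is recovered in ≈ 99% of 500 seeded replicates (the test asserts
≥ 95%).

A gene whose expression persists across all exons has, by convention, last
expressed exon = n_exons; this is how a truncation at the final exon (a
breakpoint at or beyond the gene's 3′ end) is reconciled with a fusion
junction there.  Consistency between a coverage changepoint and a fusion
breakpoint exon is declared at |Δ| ≤ 1 exon.

## Expression context

TPM per sample: `rate_g = counts_g / length_kb_g`,
`TPM_g = 10⁶ · rate_g / Σ rate`.  Gene length is the summed exonic length
of the canonical model.  A case value is placed in the cohort at its
midrank percentile, `100 · (#below + ½·#equal)/n`, and called elevated at
the 90th percentile (configurable).  Group contrasts use the probability
of superiority — the fraction of case-versus-cohort pairs where the case
value is larger, ties half — computed from pooled midranks (equivalent to
Mann–Whitney U / (n₁n₂), cross-checked in tests against both an all-pairs
count and `scipy.stats.mannwhitneyu`).

## Per-case integration

Evidence hierarchy: a primary fusion call involving the gene of interest
is classified by geometry and frame; with no call, the gene's coverage is
examined for a truncation; with neither, the case is flagged
("insufficient evidence" when coverage is missing, "no alteration
detected" when coverage is flat), never silently passed.  Methylation
class and integrated diagnosis are input metadata: tabulated, never
computed.  Cohort medians use the midpoint-of-middle-two convention; on
the bundled cohort's recorded integer ages this gives 11.5, and the report
surfaces the computed value rather than forcing agreement with the usual
rounded quote of 11.

## Synthetic data

The 14-case fixture bundles are deterministic and encode one event class
per case: head-to-tail frame-matched junctions (productive), head-to-tail
frame-mismatched junctions, tail-to-tail junctions, intergenic partners,
and one caller-negative case whose coverage drops after exon 10.  Junction
exons the source cohort does not pin down (the MYB::QKI junction exon, the
second intergenic MYB case's truncation exon, the MYBL1 junction exons)
were fixed once at round in-CDS exon boundaries: MYB exon 11 for the
MYB::QKI fusions, exon 12 for the second intergenic case, MYBL1 exon 9 for
the MMP16 fusions and exon 7 for the KHDRBS3 fusion.  Fixture coverage
tables are noise-free (40 reads on every expressed 200-nt exon, a 1/0
alternation downstream of the break, ≈ 67-fold drops).

The simulators add the stochastic structure: fusion calls with labeled
ground truth realized through residue-matched or mismatched coding
offsets; Poisson exon counts at configurable pre/post densities; and a
log-normal expression cohort (σ = 0.7 on the natural-log scale) of 1005
reference samples plus a study group with configurable log2 shifts on QKI
(default +1.5) and the genes of interest (default +3).  The simulated
panel has only 53 genes, so absolute TPM values are inflated relative to a
transcriptome-wide library — percentiles and rank statistics, which are
what the package reports, are unaffected.  What passing tests show is that
the classifier and detector are correct for the geometry and noise models
stated here; they do not certify behavior on real libraries with FFPE
degradation, 3′ bias, alignment artifacts or multi-break events.

## Problem sizes

Default test and calibration sizes: 500 labeled fusion simulations, 500
coverage replicates, a 1005-sample cohort — chosen to estimate the rates
of interest with Monte-Carlo error well inside the asserted margins while
keeping the full suite in a few seconds.
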