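"""Coverage changepoint detection for cryptic truncations."""

import math

import numpy as np
import pytest

from fusionframe.coverage_truncation import (
    ExonCoverageProfile,
    detect_truncation,
    exon_density,
    last_expressed_exon,
    truncation_consistency,
)
from fusionframe.synthetic_data import SimulationConfig, simulate_coverage


def profile(counts, lengths=None, case_id="t", gene="MYB", background=None):
    lengths = lengths or [200] * len(counts)
    return ExonCoverageProfile(case_id, gene, tuple(counts), tuple(lengths), background)


def oracle_changepoint(densities):
    """Independent exhaustive-search re-implementation of the two-segment
    Gaussian likelihood on log1p densities (plain loops, shared variance)."""
    y = [math.log1p(d) for d in densities]
    n = len(y)

    def rss(seg):
        m = sum(seg) / len(seg)
        return sum((v - m) ** 2 for v in seg)

    best_k, best = 1, -math.inf
    total = max(rss(y), 1e-9)
    for k in range(1, n):
        gain = 0.5 * n * math.log(total / max(rss(y[:k]) + rss(y[k:]), 1e-9))
        if gain > best:
            best_k, best = k, gain
    return best_k


class TestExonDensity:
    def test_reads_per_kilobase(self):
        assert exon_density(profile([100], [1000])).tolist() == [100.0]
        assert exon_density(profile([50, 50], [500, 1000])).tolist() == [100.0, 50.0]

    def test_matches_elementwise_computation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 500, size=12).tolist()
        lengths = rng.integers(50, 2000, size=12).tolist()
        dens = exon_density(profile(counts, lengths))
        for d, c, l in zip(dens, counts, lengths):
            assert d == pytest.approx(1000.0 * c / l)

    def test_zero_length_exon_rejected(self):
        with pytest.raises(ValueError):
            exon_density(profile([1, 1, 1], [100, 0, 100]))


class TestDetectTruncation:
    def test_case9_fixture_drops_after_exon_10(self, bundles):
        tc = detect_truncation(bundles["9"].coverage)
        assert tc.truncated and tc.last_expressed_exon == 10
        assert tc.fold_drop >= 10

    def test_flat_profile_not_truncated(self):
        tc = detect_truncation(profile([20] * 10))
        assert not tc.truncated and tc.last_expressed_exon is None

    def test_all_zero_profile_warns_no_expression(self):
        with pytest.warns(UserWarning, match="no expression"):
            tc = detect_truncation(profile([0, 0, 0, 0]))
        assert not tc.truncated

    def test_argmax_matches_exhaustive_oracle_on_poisson_replicates(self):
        cfg = SimulationConfig(seed=0)
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = int(rng.integers(1, cfg.n_exons))
            prof = simulate_coverage(cfg, k, rng=rng)
            dens = exon_density(prof)
            tc = detect_truncation(prof)
            expect = oracle_changepoint(dens.tolist())
            if tc.truncated:
                assert tc.last_expressed_exon == expect

    def test_recovery_rate_on_strong_dropoff(self):
        """True truncation exon recovered in >= 95% of 500 seeded
        replicates at 200 vs 2 reads/kb over 15 exons."""
        cfg = SimulationConfig(seed=0, n_exons=15, pre_density=200.0, post_density=2.0)
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(500):
            k = int(rng.integers(1, cfg.n_exons))
            tc = detect_truncation(simulate_coverage(cfg, k, rng=rng))
            hits += tc.truncated and tc.last_expressed_exon == k
        assert hits / 500 >= 0.95

    def test_background_reference_gate_relaxes_post_cap(self):
        # post density 15/kb: a 6.7-fold drop that fails the 10% post cap of
        # pre=100/kb but sits within a background reference of 20/kb
        counts = [20] * 6 + [3] * 4  # 100/kb then 15/kb on 200-nt exons
        assert not detect_truncation(profile(counts), min_fold=5).truncated
        assert detect_truncation(profile(counts, background=20.0), min_fold=5).truncated

    def test_fewer_than_three_exons_rejected(self):
        with pytest.raises(ValueError, match="3 exons"):
            detect_truncation(profile([10, 1]))


class TestInvariants:
    @pytest.mark.parametrize("scale", [2, 10, 100])
    def test_changepoint_invariant_to_depth_scaling(self, bundles, scale):
        base = bundles["9"].coverage
        scaled = ExonCoverageProfile(
            base.case_id,
            base.gene_symbol,
            tuple(c * scale for c in base.exon_counts),
            base.exon_lengths,
        )
        a, b = detect_truncation(base), detect_truncation(scaled)
        assert (a.truncated, a.last_expressed_exon) == (b.truncated, b.last_expressed_exon)

    def test_raising_min_fold_never_creates_truncations(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(seed=0, post_density=30.0)
        for _ in range(50):
            prof = simulate_coverage(cfg, int(rng.integers(1, 15)), rng=rng)
            verdicts = [
                detect_truncation(prof, min_fold=f).truncated for f in (2, 5, 10, 50)
            ]
            # once false at a lower threshold, never true at a higher one
            assert verdicts == sorted(verdicts, reverse=True)


class TestConsistency:
    def test_case3_changepoint_agrees_with_fusion_exon(self, bundles):
        tc = detect_truncation(bundles["3"].coverage)
        assert truncation_consistency(tc, 9) == "consistent"

    def test_case7_persistent_coverage_consistent_with_last_exon(self, bundles):
        cov = bundles["7"].coverage
        tc = detect_truncation(cov)
        assert not tc.truncated
        assert last_expressed_exon(cov) == 15
        assert truncation_consistency(tc, 15, n_exons=cov.n_exons) == "consistent"

    def test_distant_exons_inconsistent(self, bundles):
        tc = detect_truncation(bundles["9"].coverage)  # last exon 10
        assert truncation_consistency(tc, 3) == "inconsistent"

    def test_no_fusion_exon(self, bundles):
        tc = detect_truncation(bundles["9"].coverage)
        assert truncation_consistency(tc, None) == "no_fusion"
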