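"""Insulation scores, permutation/bootstrap tests and accessibility profiles."""

import numpy as np
import pytest

from chromloop.intervals import Genome, GenomicInterval, Loop
from chromloop.io import SignalTrack
from chromloop.insulation import (
    expression_score,
    gene_body_profile,
    insulation_null,
    insulation_score,
    low_accessibility_subset,
    peak_accessibility_test,
    permutation_overlap_test,
    tss_profile,
)
from chromloop.simulate import SimulationConfig, generate_dataset


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def make_loop(chrom, s, e, anchor=100):
    return Loop(iv(chrom, s, s + anchor), iv(chrom, e - anchor, e))


class TestExpressionScore:
    @pytest.mark.parametrize(
        "counts, length, expected",
        [(0, 1000, -2.0), (990, 1000, 0.0), (9990, 1000, 1.0)],
    )
    def test_pseudocounted_log(self, counts, length, expected):
        assert expression_score(counts, length) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expression_score(-1, 100)
        with pytest.raises(ValueError):
            expression_score(1, 0)


class TestInsulationScore:
    genome = Genome({"chr1": 100_000})

    def setup_scene(self, offset=0):
        """Loop span [10k, 20k) + offset; two genes inside, one per flank."""
        genes = [
            iv("chr1", 11_000 + offset, 12_000 + offset, name="in1"),
            iv("chr1", 15_000 + offset, 16_000 + offset, name="in2"),
            iv("chr1", 2_000 + offset, 3_000 + offset, name="left"),
            iv("chr1", 25_000 + offset, 26_000 + offset, name="right"),
        ]
        expr = {"in1": 1.0, "in2": 2.0, "left": 0.5, "right": 0.7}
        loop = make_loop("chr1", 10_000 + offset, 20_000 + offset)
        return loop, genes, expr

    def test_hand_computed_example(self):
        loop, genes, expr = self.setup_scene()
        res = insulation_score(loop, genes, expr, self.genome)
        assert res.inside_mean == pytest.approx(1.5)
        assert res.flank_mean == pytest.approx(0.6)
        assert res.score == pytest.approx(0.9)
        assert res.n_inside == 2 and res.n_flank == 2
        assert res.valid

    def test_translation_invariance(self):
        genome = Genome({"chr1": 500_000})
        loop0, genes0, expr = self.setup_scene(0)
        loop1, genes1, _ = self.setup_scene(137_000)
        r0 = insulation_score(loop0, genes0, expr, genome)
        r1 = insulation_score(loop1, genes1, expr, genome)
        assert r0.score == pytest.approx(r1.score)

    def test_equal_means_score_zero(self):
        loop, genes, _ = self.setup_scene()
        expr = {"in1": 1.0, "in2": 1.0, "left": 1.0, "right": 1.0}
        assert insulation_score(loop, genes, expr, self.genome).score == 0.0

    def test_flank_clipped_at_chromosome_start(self):
        # loop at the chromosome start: left flank is empty space
        loop = make_loop("chr1", 0, 10_000)
        genes = [
            iv("chr1", 1_000, 2_000, name="in1"),
            iv("chr1", 15_000, 16_000, name="right"),
        ]
        expr = {"in1": 2.0, "right": 1.0}
        res = insulation_score(loop, genes, expr, self.genome)
        assert res.valid and res.n_flank == 1
        assert res.score == pytest.approx(1.0)

    def test_empty_flank_flagged_invalid(self):
        loop, genes, expr = self.setup_scene()
        only_inside = [g for g in genes if g.name.startswith("in")]
        res = insulation_score(loop, only_inside, expr, self.genome)
        assert not res.valid


class TestInsulationNull:
    def test_constant_expression_gives_zero_scores(self):
        genome = Genome({"chr1": 1_000_000})
        rng = np.random.default_rng(0)
        genes = [
            iv("chr1", int(s), int(s) + 500, name=f"g{i}")
            for i, s in enumerate(range(0, 1_000_000, 10_000))
        ]
        expr = {g.name: 3.0 for g in genes}
        loops = [make_loop("chr1", 100_000, 150_000)]
        res = insulation_null(loops, genes, expr, genome, seed=1, n=5)
        assert np.all(res["observed_scores"] == 0.0)
        assert np.all(res["null_scores"] == 0.0)

    def test_planted_shift_detected(self, default_bundle, wt_expression_scores):
        b = default_bundle
        res = insulation_null(
            b.loops_a[:150], b.genes, wt_expression_scores, b.genome, seed=5, n=10
        )
        assert np.median(res["observed_scores"]) > np.median(res["null_scores"])
        assert res["pvalue"] < 0.01

    def test_silent_under_null(self):
        cfg = SimulationConfig(seed=9, insulation_shift=0.0, n_genes=800)
        b = generate_dataset(cfg)
        expr = {
            g.name: expression_score(b.expression[g.name].wt_count, g.length)
            for g in b.genes
        }
        res = insulation_null(b.loops_a[:150], b.genes, expr, b.genome, seed=2, n=10)
        assert res["pvalue"] >= 0.01

    def test_deterministic(self, default_bundle, wt_expression_scores):
        b = default_bundle
        kw = dict(seed=3, n=2)
        r1 = insulation_null(b.loops_a[:20], b.genes, wt_expression_scores, b.genome, **kw)
        r2 = insulation_null(b.loops_a[:20], b.genes, wt_expression_scores, b.genome, **kw)
        assert np.array_equal(r1["null_scores"], r2["null_scores"])


class TestPermutationOverlapTest:
    genome = Genome({"chr1": 200_000})

    def test_p_on_grid_and_in_unit_interval(self):
        rng = np.random.default_rng(4)
        a = [iv("chr1", int(s), int(s) + 500) for s in rng.integers(0, 150_000, 20)]
        b = [iv("chr1", int(s), int(s) + 500) for s in rng.integers(0, 150_000, 20)]
        res = permutation_overlap_test(a, b, self.genome, seed=0, n=50)
        assert 0.0 <= res["pvalue"] <= 1.0
        assert res["pvalue"] * 50 == pytest.approx(round(res["pvalue"] * 50))

    def test_strong_overlap_yields_zero_p(self):
        a = [iv("chr1", s, s + 100) for s in range(0, 200_000, 10_000)]
        res = permutation_overlap_test(a, a, self.genome, seed=1, n=100)
        assert res["observed"] == len(a)
        assert res["pvalue"] == 0.0
        assert res["enrichment"] > 1.0

    def test_conservative_smoothing(self):
        a = [iv("chr1", s, s + 100) for s in range(0, 200_000, 10_000)]
        res = permutation_overlap_test(
            a, a, self.genome, seed=1, n=100, conservative=True
        )
        assert res["pvalue"] == pytest.approx(1 / 101)

    def test_deterministic(self):
        a = [iv("chr1", 1000, 2000), iv("chr1", 50_000, 51_000)]
        b = [iv("chr1", 1500, 2500)]
        r1 = permutation_overlap_test(a, b, self.genome, seed=7, n=20)
        r2 = permutation_overlap_test(a, b, self.genome, seed=7, n=20)
        assert np.array_equal(r1["null_counts"], r2["null_counts"])


class TestPeakAccessibility:
    def test_window_geometry_center_plus_minus_flank(self):
        # width-1 peak at c: the scored window is [c-250, c+251)
        genome = Genome({"chr1": 10_000})
        c = 5000
        track = SignalTrack.from_tuples(
            [("chr1", c - 250, c + 251, 7.0)]
        )
        peaks = [iv("chr1", c, c + 1)]
        res = peak_accessibility_test(peaks, track, genome, seed=0, n=5)
        assert res["scores"][0] == pytest.approx(np.log10(7.0))

    def test_planted_signal_gives_zero_p(self, default_bundle):
        b = default_bundle
        res = peak_accessibility_test(b.peaks, b.track_wt, b.genome, seed=0, n=100)
        assert res["real_mean"] > res["null_means"].max()
        assert res["pvalue"] == 0.0

    def test_constant_track_p_not_degenerate(self):
        genome = Genome({"chr1": 1_000_000})
        track = SignalTrack.from_tuples([("chr1", 0, 1_000_000, 2.0)])
        rng = np.random.default_rng(11)
        peaks = [iv("chr1", int(s), int(s) + 200) for s in rng.integers(0, 900_000, 30)]
        res = peak_accessibility_test(peaks, track, genome, seed=1, n=100)
        # constant signal: permuted means tie with the real mean; the strict
        # "bigger than" rule then never counts, so p stays at the boundary
        assert 0.0 <= res["pvalue"] <= 1.0

    def test_p_monotone_in_signal_ratio(self):
        """Bootstrap p decreases (weakly) as planted peak signal grows."""
        genome = Genome({"chr1": 2_000_000})
        rng = np.random.default_rng(3)
        centers = np.sort(rng.integers(2000, 1_998_000, 25))
        pvals = []
        for ratio in [1.0, 2.0, 5.0, 20.0]:
            rows = []
            pos = 0
            for c in centers:
                w0, w1 = int(c) - 250, int(c) + 251
                if w0 > pos:
                    rows.append(("chr1", pos, w0, 1.0))
                rows.append(("chr1", w0, w1, ratio))
                pos = w1
            rows.append(("chr1", pos, 2_000_000, 1.0))
            track = SignalTrack.from_tuples(rows)
            peaks = [iv("chr1", int(c), int(c) + 1) for c in centers]
            res = peak_accessibility_test(peaks, track, genome, seed=9, n=50)
            pvals.append(res["pvalue"])
        assert all(p1 >= p2 for p1, p2 in zip(pvals, pvals[1:]))
        assert pvals[-1] == 0.0

    def test_empty_inputs_rejected(self, default_bundle):
        with pytest.raises(ValueError):
            peak_accessibility_test(
                [], default_bundle.track_wt, default_bundle.genome, seed=0
            )
        empty = SignalTrack({})
        with pytest.raises(ValueError):
            peak_accessibility_test(
                default_bundle.peaks, empty, default_bundle.genome, seed=0
            )


class TestLowAccessibilitySubset:
    def test_planted_cold_sites_recovered(self, default_bundle):
        b = default_bundle
        low = low_accessibility_subset(b.peaks, b.track_wt, b.genome, seed=0, n=10)
        recovered = {p.name for p in low}
        cold = {p.name for p in b.peaks if p.name.endswith("_cold")}
        assert recovered == cold
        # planted cold fraction ~5%
        assert 0.02 <= len(cold) / len(b.peaks) <= 0.08

    def test_all_hot_gives_empty_subset(self):
        genome = Genome({"chr1": 1_000_000})
        track = SignalTrack.from_tuples(
            [("chr1", 0, 100_000, 10.0), ("chr1", 100_000, 1_000_000, 1.0)]
        )
        peaks = [iv("chr1", s, s + 100) for s in range(10_000, 90_000, 10_000)]
        low = low_accessibility_subset(peaks, track, genome, seed=2, n=10)
        assert low == []

    def test_deterministic(self, default_bundle):
        b = default_bundle
        l1 = low_accessibility_subset(b.peaks, b.track_wt, b.genome, seed=8, n=3)
        l2 = low_accessibility_subset(b.peaks, b.track_wt, b.genome, seed=8, n=3)
        assert l1 == l2


class TestProfiles:
    genome_len = 100_000

    def test_tss_profile_zero_when_ko_equals_wt(self):
        track = SignalTrack.from_tuples([("chr1", 0, self.genome_len, 3.0)])
        genes = [iv("chr1", 50_000, 60_000, strand="+", name="g")]
        prof = tss_profile(genes, track, track)
        assert prof.shape == (2001,)
        assert np.allclose(prof, 0.0)

    def test_tss_profile_piecewise_halving(self):
        # KO halved only in [TSS-100, TSS+100): -1 inside, 0 outside, up to
        # the pseudocount perturbation
        tss = 50_000
        wt = SignalTrack.from_tuples([("chr1", 0, self.genome_len, 4.0)])
        ko = SignalTrack.from_tuples(
            [
                ("chr1", 0, tss - 100, 4.0),
                ("chr1", tss - 100, tss + 100, 2.0),
                ("chr1", tss + 100, self.genome_len, 4.0),
            ]
        )
        genes = [iv("chr1", tss, tss + 5000, strand="+", name="g")]
        prof = tss_profile(genes, wt, ko)
        inner = prof[1000 - 100 : 1000 + 100]
        outer = np.concatenate([prof[: 1000 - 100], prof[1000 + 100 :]])
        assert np.allclose(inner, np.log2(2.01 / 4.01))
        assert np.allclose(outer, 0.0)

    def test_tss_profile_minus_strand_flipped(self):
        # depletion downstream of a minus-strand TSS must appear at positive
        # offsets after flipping
        wt = SignalTrack.from_tuples([("chr1", 0, self.genome_len, 4.0)])
        gene = iv("chr1", 40_000, 50_000, strand="-", name="g")
        tss = 50_000 - 1
        ko = SignalTrack.from_tuples(
            [
                ("chr1", 0, tss - 500, 4.0),
                ("chr1", tss - 500, tss, 2.0),  # genomic left = downstream
                ("chr1", tss, self.genome_len, 4.0),
            ]
        )
        prof = tss_profile([gene], wt, ko)
        assert np.allclose(prof[1001:1501], np.log2(2.01 / 4.01))
        assert np.allclose(prof[:1000], 0.0)

    def test_gene_body_profile_flat_and_depleted(self):
        wt = SignalTrack.from_tuples([("chr1", 0, self.genome_len, 4.0)])
        genes = [iv("chr1", 30_000, 40_000, strand="+", name="g")]
        flat = gene_body_profile(genes, wt, wt, n_bins=10, flank_bins=4)
        assert flat.shape == (18,)
        assert np.allclose(flat, 0.0)
        ko = SignalTrack.from_tuples(
            [
                ("chr1", 0, 30_000, 4.0),
                ("chr1", 30_000, 40_000, 1.0),
                ("chr1", 40_000, self.genome_len, 4.0),
            ]
        )
        prof = gene_body_profile(genes, wt, ko, n_bins=10, flank_bins=4)
        body = prof[4:14]
        flanks = np.concatenate([prof[:4], prof[14:]])
        assert np.allclose(body, np.log2(1.01 / 4.01))
        assert np.allclose(flanks, 0.0)

    def test_short_gene_skipped(self, caplog):
        import logging

        wt = SignalTrack.from_tuples([("chr1", 0, self.genome_len, 4.0)])
        genes = [
            iv("chr1", 30_000, 30_005, strand="+", name="tiny"),
            iv("chr1", 50_000, 60_000, strand="+", name="ok"),
        ]
        with caplog.at_level(logging.WARNING, logger="chromloop"):
            prof = gene_body_profile(genes, wt, wt, n_bins=10, flank_bins=2)
        assert "skipped 1" in caplog.text
        assert prof.shape == (14,)
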