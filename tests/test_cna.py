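"""Copy-number model: log-ratios, segmentation, purity/ploidy fit, calling."""
import numpy as np
import pandas as pd
import pytest

from panelvar.cna import (
    LogRatioProfile,
    PurityPloidyModel,
    call_focal_cnas,
    compute_logratios,
    expected_baf,
    expected_logratio,
    fit_purity_ploidy,
    segment_profile,
)
from panelvar.simulate import simulate_logratio_profile, simulate_snp_bafs


def coverage_frame(exons, cov):
    df = exons.copy()
    df["coverage"] = cov
    return df


class TestExpectedValues:
    @pytest.mark.parametrize("p", [0.1, 0.5, 1.0])
    def test_neutral_state_is_zero(self, p):
        assert expected_logratio(2, p, 2.0) == 0.0

    def test_known_points(self):
        assert expected_logratio(6, 0.5, 2.0) == pytest.approx(1.0)
        assert expected_logratio(4, 1.0, 2.0) == pytest.approx(1.0)

    def test_floor_replaces_minus_infinity(self):
        assert expected_logratio(0, 1.0, 2.0) == -8.0

    def test_strictly_increasing_in_copies(self):
        for p in (0.2, 0.6, 1.0):
            vals = expected_logratio(np.arange(0, 10), p, 2.0)
            assert (np.diff(vals) > 0).all()

    def test_expected_baf_points(self):
        assert expected_baf(2, 1, 0.37) == 0.5
        assert expected_baf(2, 0, 1.0) == 0.0
        assert expected_baf(3, 1, 0.6) == pytest.approx((0.6 + 0.4) / (1.8 + 0.8))
        with pytest.raises(ValueError):
            expected_baf(2, 3, 0.5)


class TestComputeLogratios:
    def exons(self, n=30):
        return pd.DataFrame({
            "contig": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 150, "gene": "G1",
        })

    def test_equal_coverage_gives_zeros(self):
        e = self.exons()
        prof = compute_logratios(coverage_frame(e, 500.0),
                                 coverage_frame(e, 500.0))
        assert np.allclose(prof.lr, 0.0)

    def test_global_scaling_removed_by_median_centering(self):
        e = self.exons()
        prof = compute_logratios(coverage_frame(e, 1000.0),
                                 coverage_frame(e, 500.0))
        assert np.allclose(prof.lr, 0.0)

    def test_focal_gain_stands_out_after_centering(self):
        e = self.exons()
        cov = np.full(30, 400.0)
        cov[10:13] = 1600.0  # one gene's exons at 4x
        prof = compute_logratios(coverage_frame(e, cov),
                                 coverage_frame(e, 400.0))
        assert np.allclose(prof.lr[10:13], 2.0)
        assert np.allclose(np.delete(prof.lr, [10, 11, 12]), 0.0)

    def test_low_normal_coverage_dropped_and_logged(self):
        e = self.exons()
        n_cov = np.full(30, 300.0)
        n_cov[5] = 2.0
        log = []
        prof = compute_logratios(coverage_frame(e, 300.0),
                                 coverage_frame(e, n_cov), log=log)
        assert len(prof) == 29
        assert len(log) == 1

    def test_disjoint_exons_error(self):
        e1, e2 = self.exons(), self.exons()
        e2["start"] += 7
        with pytest.raises(ValueError):
            compute_logratios(coverage_frame(e1, 100.0),
                              coverage_frame(e2, 100.0))


class TestSegmentation:
    def test_noiseless_step_is_split_exactly(self):
        lr = np.concatenate([np.zeros(40), np.full(40, 1.0)])
        segs = segment_profile(lr)
        assert [(s.start, s.end) for s in segs] == [(0, 40), (40, 80)]
        assert segs[0].mean == 0.0 and segs[1].mean == 1.0

    def test_flat_noisy_profile_stays_single_segment(self):
        rng = np.random.default_rng(5)
        segs = segment_profile(rng.normal(0, 0.1, 3230))
        assert len(segs) == 1

    def test_five_level_profile_breakpoints_within_two_exons(self):
        rng = np.random.default_rng(11)
        levels = [0.0, 0.58, -1.0, 0.32, 1.0]
        lr = np.concatenate([np.full(30, v) for v in levels])
        lr += rng.normal(0, 0.15, lr.size)
        segs = segment_profile(lr)
        found = sorted(s.start for s in segs[1:])
        assert len(found) == 4
        for true_bp, got in zip([30, 60, 90, 120], found):
            assert abs(got - true_bp) <= 2

    def test_segments_partition_profile(self):
        rng = np.random.default_rng(3)
        lr = rng.normal(0, 0.3, 200)
        segs = segment_profile(lr)
        assert segs[0].start == 0 and segs[-1].end == 200
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start


class TestPurityPloidyFit:
    def simulate(self, seed, p_true, noise=0.1):
        rng = np.random.default_rng(seed)
        copies = np.repeat([0, 1, 2, 3, 4, 6], 25)
        minor = np.repeat([0, 0, 1, 1, 1, 1], 25)
        prof = simulate_logratio_profile(copies, p_true, 2.0, noise, seed=rng)
        segs = segment_profile(prof)
        bafs = simulate_snp_bafs(copies, minor, p_true, n_snps=60, depth=100,
                                 seed=rng)
        seg_of = np.empty(copies.size, int)
        for si, s in enumerate(segs):
            seg_of[s.start:s.end] = si
        bafs["segment"] = seg_of[bafs["segment"].to_numpy()]
        return prof, segs, bafs, copies

    def test_recovery_over_twenty_replicates(self):
        """Purity within +-0.05, ploidy within +-0.2 and exact segment copy
        numbers across 20 seeded tumors with p in [0.3, 0.9]."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            p_true = rng.uniform(0.3, 0.9)
            prof, segs, bafs, copies = self.simulate(seed, p_true)
            fit = PurityPloidyModel(segs, bafs=bafs, profile=prof).fit()
            assert fit.identifiable
            assert abs(fit.purity - p_true) <= 0.05
            assert abs(fit.ploidy - 2.0) <= 0.2
            if len(fit.segments) == 6:
                assert [s.copies for s in fit.segments] == [0, 1, 2, 3, 4, 6]

    def test_flat_profile_unidentifiable(self):
        prof = simulate_logratio_profile(np.full(80, 2), 0.7, 2.0, 0.05, seed=1)
        fit = fit_purity_ploidy(segment_profile(prof), profile=prof)
        assert not fit.identifiable
        assert fit.purity is None

    def test_coarser_grid_containing_truth_gives_same_argmax(self):
        prof, segs, bafs, _ = self.simulate(0, 0.7, noise=0.05)
        fine = PurityPloidyModel(segs, bafs=bafs, profile=prof).fit()
        coarse = PurityPloidyModel(
            segs, bafs=bafs, profile=prof,
            purity_grid=np.round(np.arange(0.1, 1.001, 0.05), 10),
            ploidy_grid=np.array([1.5, 2.0, 3.0, 4.0]),
        ).fit()
        assert coarse.ploidy == pytest.approx(fine.ploidy, abs=0.1)
        assert coarse.purity == pytest.approx(fine.purity, abs=0.05)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PurityPloidyModel([], purity_grid=np.array([]))

    def test_summary_reports_fit(self):
        prof, segs, bafs, _ = self.simulate(2, 0.6)
        res = PurityPloidyModel(segs, bafs=bafs, profile=prof).fit()
        s = res.summary()
        assert "purity" in s and "tumor ploidy" in s


def hand_fit(seg_copies, purity, ploidy=2.0, n_exons=10, identifiable=True):
    """Construct a PurityPloidyResults with prescribed segment copies."""
    from panelvar.cna import PurityPloidyResults, Segment

    segs = []
    start = 0
    for c in seg_copies:
        mean = expected_logratio(c, purity, ploidy)
        segs.append(Segment(start, start + n_exons, mean, n_exons, copies=c))
        start += n_exons
    model = PurityPloidyModel(segs)
    return PurityPloidyResults(model, purity, ploidy, segs, 0.0,
                               identifiable, 0.1)


class TestFocalCalls:
    def test_amplified_gene_called_at_six_copies(self):
        fit = hand_fit([2, 6, 2], purity=0.6)
        calls = call_focal_cnas(fit, {"CCND1": range(10, 20),
                                      "BG": range(0, 10)})
        assert [(c.gene, c.kind, c.copies) for c in calls] == [
            ("CCND1", "amplification", 6)]

    def test_five_copies_not_called(self):
        fit = hand_fit([2, 5, 2], purity=0.6)
        assert call_focal_cnas(fit, {"G": range(10, 20)}) == []

    def test_homozygous_deletion_called(self):
        fit = hand_fit([2, 0, 2], purity=0.5)
        calls = call_focal_cnas(fit, {"CDKN2A": range(10, 20)})
        assert [(c.gene, c.kind, c.copies) for c in calls] == [
            ("CDKN2A", "homozygous_deletion", 0)]

    def test_purity_gate_suppresses_calls(self):
        """No CNA call is ever emitted at purity <= 20%, even for a clear
        homozygous deletion."""
        log = []
        fit = hand_fit([2, 0, 2], purity=0.15)
        assert call_focal_cnas(fit, {"CDKN2A": range(10, 20)}, log=log) == []
        assert any("purity" in m for m in log)

    def test_gate_exhaustive_over_purity_grid(self):
        gene_map = {"A": range(0, 10), "B": range(10, 20)}
        for purity in np.round(np.arange(0.05, 1.0, 0.05), 10):
            fit = hand_fit([0, 6], purity=purity)
            calls = call_focal_cnas(fit, gene_map)
            if purity <= 0.20:
                assert calls == []
            else:
                assert len(calls) == 2

    def test_unidentifiable_fit_emits_nothing(self):
        fit = hand_fit([2, 6, 2], purity=0.6, identifiable=False)
        log = []
        assert call_focal_cnas(fit, {"G": range(10, 20)}, log=log) == []

    def test_modal_reduction_ties_toward_extreme(self):
        # gene spans two segments equally: 2 copies and 8 copies -> extreme
        fit = hand_fit([2, 8], purity=0.9)
        calls = call_focal_cnas(fit, {"G": range(5, 15)})
        assert [(c.gene, c.copies) for c in calls] == [("G", 8)]

    def test_gene_without_exons_skipped(self):
        fit = hand_fit([4], purity=0.9)
        log = []
        calls = call_focal_cnas(fit, {"NOWHERE": []}, log=log)
        assert calls == [] and any("NOWHERE" in m for m in log)

    def test_fit_to_call_roundtrip_with_bafs(self):
        """End-to-end on an identifiable multi-state tumor: the fitted copy
        numbers drive correct amplification and deletion calls."""
        rng = np.random.default_rng(17)
        copies = np.repeat([2, 0, 2, 6, 2, 3], 20)
        minor = np.repeat([1, 0, 1, 1, 1, 1], 20)
        prof = simulate_logratio_profile(copies, 0.6, 2.0, 0.1, seed=rng)
        segs = segment_profile(prof)
        bafs = simulate_snp_bafs(copies, minor, 0.6, n_snps=60, depth=150,
                                 seed=rng)
        seg_of = np.empty(copies.size, int)
        for si, s in enumerate(segs):
            seg_of[s.start:s.end] = si
        bafs["segment"] = seg_of[bafs["segment"].to_numpy()]
        fit = PurityPloidyModel(segs, bafs=bafs, profile=prof).fit()
        assert abs(fit.purity - 0.6) <= 0.05
        gene_map = {"DEL_GENE": range(20, 40), "AMP_GENE": range(60, 80),
                    "BG": range(0, 20)}
        calls = {c.gene: c for c in call_focal_cnas(fit, gene_map)}
        assert calls["DEL_GENE"].kind == "homozygous_deletion"
        assert calls["AMP_GENE"].kind == "amplification"
        assert "BG" not in calls
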