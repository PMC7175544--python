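"""Segmental Z-scores, aberration calls, CPA, and cutoff calibration."""

import numpy as np
import pytest
from scipy import stats

from cfcna import (BinGrid, CopyNumberProfile, CpaResult, ReferencePanel,
                   Segment, SegmentSet, UndeterminableSegmentError,
                   calibrate_cutoff, call_segment, classify_abnormal,
                   cpa_score, lilliefors_normality, segment_zscore)


def _grid(n_bins):
    return BinGrid.from_chromosomes([("1", n_bins * 100_000)],
                                    bin_width=100_000)


def _segment(grid, mean=0.0, z=np.nan, length_bp=None, call="unset",
             determinable=True):
    return Segment("1", 0, grid.n_bins - 1, mean,
                   length_bp or grid.n_bins * 100_000, grid.n_bins,
                   z_score=z, call=call, determinable=determinable)


class TestSegmentZscore:
    def test_constant_controls_worked_example(self):
        """5 controls with constant ratios {-0.2..0.2}, case mean 0.3:
        Z = 0.3 / population-sd(0.14142) = 2.1213."""
        grid = _grid(4)
        panel = ReferencePanel(grid, np.tile(
            np.array([[-0.2], [-0.1], [0.0], [0.1], [0.2]]), (1, 4)))
        prof = CopyNumberProfile("case", grid, np.full(4, 0.3))
        z = segment_zscore(prof, panel, grid, _segment(grid))
        assert z == pytest.approx(0.3 / np.std([-0.2, -0.1, 0, 0.1, 0.2]),
                                  abs=1e-12)
        assert z == pytest.approx(2.1213, abs=1e-4)

    def test_case_at_control_mean_scores_zero(self, rng):
        grid = _grid(6)
        panel = ReferencePanel(grid, rng.normal(0, 0.1, (5, 6)))
        mu_ctrl = panel.control_ratios.mean(axis=1).mean()
        prof = CopyNumberProfile("case", grid, np.full(6, np.nan))
        # a case whose weighted mean equals the control mean-of-means
        prof.ratios[:] = mu_ctrl
        z = segment_zscore(prof, panel, grid, _segment(grid))
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self, rng):
        grid = _grid(8)
        base = rng.normal(0, 0.1, (6, 8))
        case = rng.normal(0.2, 0.1, 8)
        z0 = segment_zscore(CopyNumberProfile("c", grid, case),
                            ReferencePanel(grid, base), grid, _segment(grid))
        c = 0.7
        z1 = segment_zscore(CopyNumberProfile("c", grid, case + c),
                            ReferencePanel(grid, base + c), grid, _segment(grid))
        assert z1 == pytest.approx(z0, abs=1e-10)

    def test_matches_direct_formula_on_random_instances(self, rng):
        """Oracle: direct evaluation of the weighted-mean/Z definition."""
        for _ in range(200):
            n = int(rng.integers(1, 11))
            p = int(rng.integers(2, 9))
            grid = _grid(n).with_weights(rng.uniform(0.5, 5, n))
            ctrl = rng.normal(0, 1, (p, n))
            case = rng.normal(0, 1, n)
            w = grid.weights
            mu_w = lambda v: np.sum(w * v) / np.sum(w)
            ctrl_means = np.array([mu_w(ctrl[k]) for k in range(p)])
            expected = (mu_w(case) - ctrl_means.mean()) / ctrl_means.std(ddof=0)
            z = segment_zscore(CopyNumberProfile("c", grid, case),
                               ReferencePanel(grid, ctrl), grid, _segment(grid))
            assert z == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_zero_control_spread_is_undeterminable(self):
        grid = _grid(3)
        panel = ReferencePanel(grid, np.zeros((4, 3)))
        prof = CopyNumberProfile("c", grid, np.full(3, 0.5))
        with pytest.raises(UndeterminableSegmentError):
            segment_zscore(prof, panel, grid, _segment(grid))


class TestCallSegment:
    @pytest.mark.parametrize("z,expected", [
        (3.0, "gain"),       # boundary: "3 or more" is aberrant
        (-3.0, "loss"),
        (-2.99, "neutral"),
        (2.99, "neutral"),
        (-5.0, "loss"),
        (0.0, "neutral"),
    ])
    def test_three_sigma_rule(self, z, expected):
        assert call_segment(z) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            call_segment(float("nan"))


class TestCpaScore:
    def test_all_zero_z_gives_zero(self):
        grid = _grid(5)
        segs = SegmentSet("s", [_segment(grid, z=0.0, call="neutral")])
        assert cpa_score(segs).cpa == 0.0

    def test_worked_instance(self):
        """(|Z|=4, 50 Mb) and (|Z|=0.5, 250 Mb), n=2 ->
        (4*0.5 + 0.5*2.5)/2 = 1.625 with lengths in 100 Mb units."""
        grid = _grid(5)
        segs = SegmentSet("s", [
            _segment(grid, z=4.0, length_bp=50_000_000, call="gain"),
            _segment(grid, z=-0.5, length_bp=250_000_000, call="neutral"),
        ])
        assert cpa_score(segs).cpa == pytest.approx(1.625, abs=1e-12)

    def test_halving_segments_with_n_doubling_halves_cpa(self):
        """Splitting every segment into two equal halves leaves the
        numerator unchanged but doubles n: CPA halves.  Documented
        segmentation-granularity sensitivity, not an invariance."""
        grid = _grid(4)
        whole = SegmentSet("s", [_segment(grid, z=2.0, length_bp=100_000_000)])
        halves = SegmentSet("s", [
            _segment(grid, z=2.0, length_bp=50_000_000),
            _segment(grid, z=2.0, length_bp=50_000_000),
        ])
        assert cpa_score(halves).cpa == pytest.approx(
            cpa_score(whole).cpa / 2, abs=1e-12)

    def test_undeterminable_segments_dropped_from_numerator_and_n(self):
        grid = _grid(4)
        segs = SegmentSet("s", [
            _segment(grid, z=4.0, length_bp=100_000_000),
            _segment(grid, determinable=False),
        ])
        assert cpa_score(segs).cpa == pytest.approx(4.0, abs=1e-12)
        assert cpa_score(segs).n_segments == 1

    def test_no_determinable_segment_signals(self):
        grid = _grid(4)
        segs = SegmentSet("s", [_segment(grid, determinable=False)])
        with pytest.raises(UndeterminableSegmentError):
            cpa_score(segs)


class TestCalibration:
    def test_cutoff_at_the_99th_normal_quantile(self, rng):
        x = rng.normal(0, 1, 200)
        x = 0.3 + 0.1 * (x - x.mean()) / x.std(ddof=1)  # exact sample stats
        calib = calibrate_cutoff(x, fdr=0.01, n_mc=200)
        assert calib.mu == pytest.approx(0.3, abs=1e-12)
        assert calib.sigma == pytest.approx(0.1, abs=1e-12)
        assert calib.cutoff == pytest.approx(0.3 + stats.norm.ppf(0.99) * 0.1,
                                             abs=1e-10)
        assert calib.cutoff == pytest.approx(0.5326, abs=1e-3)

    def test_zero_sigma_degenerates_to_mu_with_warning(self):
        with pytest.warns(UserWarning):
            calib = calibrate_cutoff(np.full(30, 0.4), fdr=0.01)
        assert calib.cutoff == pytest.approx(0.4)
        assert calib.cutoff == calib.mu

    def test_half_fdr_gives_the_median(self, rng):
        x = rng.normal(0.5, 0.2, 100)
        calib = calibrate_cutoff(x, fdr=0.5, n_mc=200)
        assert calib.cutoff == pytest.approx(calib.mu, abs=1e-12)

    def test_summary_mentions_cutoff(self, rng):
        calib = calibrate_cutoff(rng.normal(0.3, 0.1, 50), n_mc=200)
        assert "cutoff" in calib.summary()


class TestLilliefors:
    def test_normal_sample_not_rejected(self, rng):
        p = lilliefors_normality(rng.normal(5, 2, 300), n_mc=2000, seed=0)
        assert p > 0.01

    def test_exponential_sample_rejected(self, rng):
        p = lilliefors_normality(rng.exponential(1, 200), n_mc=2000, seed=0)
        assert p < 0.01

    def test_small_symmetric_sample_passes(self):
        p = lilliefors_normality(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                                 n_mc=2000, seed=0)
        assert p > 0.05

    def test_agrees_with_statsmodels_table_approximation(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        for sample in (rng.normal(0, 1, 150), rng.exponential(1, 150)):
            p_mc = lilliefors_normality(sample, n_mc=5000, seed=1)
            p_sm = sm_lilliefors(sample, dist="norm")[1]
            assert (p_mc < 0.05) == (p_sm < 0.05)
            assert abs(p_mc - min(p_sm, 0.999)) < 0.1

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            lilliefors_normality(np.full(10, 1.0))


class TestClassifyAbnormal:
    def _calib(self, cutoff, modality="liquid"):
        from cfcna import CutoffCalibration
        return CutoffCalibration(mu=0.3, sigma=0.1, fdr=0.01, cutoff=cutoff,
                                 lilliefors_p=0.5, modality=modality)

    def test_boundary_is_strictly_greater(self):
        res = classify_abnormal([CpaResult("s", 0.5, 10)], self._calib(0.5))
        assert res[0].abnormal is False
        res = classify_abnormal([CpaResult("s", 0.5001, 10)], self._calib(0.5))
        assert res[0].abnormal is True

    def test_modality_mismatch_warns(self):
        with pytest.warns(UserWarning, match="modality"):
            classify_abnormal([CpaResult("s", 0.1, 5, modality="ffpe")],
                              self._calib(0.5))
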