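"""Diversity statistic, binning, and regression fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phonosfe as ph
from phonosfe import (bin_by_distance, binned_tf, fit_cline,
                      phoneme_frequencies, t_f)


class TestFrequencies:
    def test_hand_counted_example(self):
        # masks {A,B} and {A}: p_A = 2/3, p_B = 1/3
        masks = np.array([[1, 1], [1, 0]], np.uint8)
        assert phoneme_frequencies(masks) == pytest.approx([2 / 3, 1 / 3])

    def test_identical_masks_give_uniform_over_their_phonemes(self):
        masks = np.tile([1, 0, 1, 1, 0], (4, 1))
        p = phoneme_frequencies(masks)
        assert p == pytest.approx([1 / 3, 0, 1 / 3, 1 / 3, 0])

    def test_single_mask_uniform_over_k_present_phonemes(self):
        p = phoneme_frequencies(np.array([[1, 1, 1, 0]], np.uint8))
        assert p == pytest.approx([1 / 3, 1 / 3, 1 / 3, 0])

    @pytest.mark.parametrize("bad", [np.empty((0, 5)), np.zeros((3, 5))])
    def test_empty_or_all_zero_rejected(self, bad):
        with pytest.raises(ValueError):
            phoneme_frequencies(bad)


class TestTF:
    def test_two_even_phonemes(self):
        assert t_f(np.array([0.5, 0.5])) == pytest.approx(1.0)

    def test_two_uneven_phonemes(self):
        assert t_f(np.array([0.75, 0.25])) == pytest.approx(0.6)

    @pytest.mark.parametrize("n", [2, 5, 37, 908])
    def test_uniform_closed_form(self, n):
        assert t_f(np.full(n, 1 / n)) == pytest.approx(n - 1)

    def test_single_dominant_phoneme_gives_zero(self):
        assert t_f(np.array([1.0, 0.0, 0.0])) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=30))
    def test_permutation_invariant_and_bounded_by_uniform(self, weights):
        p = np.array(weights) / np.sum(weights)
        rng = np.random.default_rng(0)
        assert t_f(rng.permutation(p)) == pytest.approx(t_f(p))
        assert t_f(p) <= (p.size - 1) + 1e-9

    def test_duplicating_a_language_moves_tf_toward_its_profile(self):
        a = np.array([1, 1, 1, 1, 0, 0], np.uint8)
        b = np.array([1, 1, 0, 0, 1, 1], np.uint8)
        base = t_f(phoneme_frequencies(np.stack([a, b])))
        dup = t_f(phoneme_frequencies(np.stack([a, b, a])))
        solo = t_f(phoneme_frequencies(np.stack([a])))
        assert abs(dup - solo) < abs(base - solo)


class TestBinning:
    def test_half_open_boundary_convention(self):
        import pandas as pd
        rec = pd.DataFrame({"distance_km": [0.0, 999.0, 1000.0]})
        bins = bin_by_distance(rec, 1000.0)
        assert [(c, len(m)) for c, m in bins] == [(500.0, 2), (1500.0, 1)]

    def test_single_record_single_bin(self):
        import pandas as pd
        bins = bin_by_distance(pd.DataFrame({"distance_km": [123.0]}), 1000.0)
        assert len(bins) == 1

    @pytest.mark.parametrize("w", [1000.0, 1500.0, 2000.0, 3000.0])
    def test_supported_widths_partition_all_records(self, w):
        import pandas as pd
        rec = pd.DataFrame({"distance_km": np.linspace(0, 24999, 360)})
        bins = bin_by_distance(rec, w)
        assert sum(len(m) for _, m in bins) == 360

    def test_binned_tf_identical_inventories_equal_k_minus_1(self):
        # every language shares one 7-phoneme inventory -> t_F = 6 per bin
        masks = np.tile(np.r_[np.ones(7, np.uint8), np.zeros(5, np.uint8)], (30, 1))
        d = np.linspace(0, 4999, 30)
        table = binned_tf(d, masks, 1000.0)
        assert table["t_F"].to_numpy() == pytest.approx(np.full(len(table), 6.0))
        assert table["n_languages"].sum() == 30


class TestFitCline:
    def test_perfect_line_recovered_exactly(self):
        x = np.linspace(0, 25000, 40)
        y = 40 - 0.001 * x
        fit = fit_cline(x, y)
        assert fit.slope == pytest.approx(-0.001)
        assert fit.r == pytest.approx(-1.0)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_gives_zero_slope(self):
        fit = fit_cline([0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 5.0, 5.0])
        assert fit.slope == 0.0
        assert fit.r == 0.0

    def test_matches_normal_equations_oracle(self, rng):
        # independent oracle: closed-form normal equations + t-based CI
        x = rng.uniform(0, 1e4, size=10)
        y = 30 - 4e-4 * x + rng.normal(0, 2, size=10)
        fit = fit_cline(x, y)
        n = x.size
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - (intercept + slope * x)
        se = np.sqrt((resid ** 2).sum() / (n - 2) / sxx)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.stderr == pytest.approx(se, rel=1e-9)
        from scipy import stats as ss
        half = ss.t.ppf(0.975, n - 2) * se
        assert fit.ci == pytest.approx((slope - half, slope + half))
        assert fit.ci_low <= fit.slope <= fit.ci_high

    @pytest.mark.parametrize("x,y", [
        ([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]),   # degenerate x
        ([1.0, 2.0], [1.0, 2.0]),             # too few points
    ])
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            fit_cline(x, y)


class TestEnsemble:
    def _tiny_config(self, loss_time=10.0):
        return ph.scaled_config(loss_time=loss_time, grid_side=21,
                                generations=400, nph=120)

    def test_distinct_seed_contract(self):
        cfg = self._tiny_config()
        with pytest.raises(ValueError):
            ph.ensemble_slopes(cfg, 2, seeds=[7, 7])
        with pytest.raises(ValueError):
            ph.ensemble_slopes(cfg, 1)

    def test_no_loss_ensemble_all_zero_slopes(self):
        import math
        scen = ph.InitialScenario(n_languages=1, phoneme_range=(37, 37))
        cfg = ph.scaled_config(loss_time=math.inf, grid_side=21,
                               generations=400, scenario=scen, nph=120)
        summary = ph.ensemble_slopes(cfg, 3, seed_base=5)
        assert summary.slopes == pytest.approx([0.0, 0.0, 0.0])
        assert summary.sigma == 0.0
        assert summary.normality_p == 1.0

    def test_interval_is_mean_plus_minus_two_sigma(self):
        cfg = self._tiny_config()
        summary = ph.ensemble_slopes(cfg, 4, seed_base=0)
        lo, hi = summary.interval
        assert hi - summary.mean == pytest.approx(2 * summary.sigma)
        assert summary.mean - lo == pytest.approx(2 * summary.sigma)
        assert len(summary.fits) == 4
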