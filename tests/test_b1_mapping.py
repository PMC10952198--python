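"""Double-angle B1+ mapping: estimators, error propagation, Monte Carlo, search."""

import numpy as np
import pytest

import vfadesign as vd
from vfadesign.b1_mapping import (
    B1Pair,
    b1_sd_error_propagation,
    b1_sd_monte_carlo,
    build_ratio_lut,
    dam_estimate_ideal,
    estimate_b1_lut,
    optimal_b1_pair,
)
from vfadesign.bloch_slice import ambiguity_angle_deg, slice_signal_magnitude


def ideal_ep_oracle(alpha_nom_deg, b1, snr, ref_deg=65.0):
    """Closed-form error propagation for the ideal sine model, k = 2."""
    a = np.deg2rad(b1 * alpha_nom_deg)
    s_a, s_2a = np.sin(a), np.sin(2 * a)
    sigma_s = np.sin(np.deg2rad(ref_deg)) / snr
    ratio = s_2a / s_a                       # = 2 cos(a)
    sigma_r = ratio * np.hypot(sigma_s / s_2a, sigma_s / s_a)
    slope = -2.0 * np.sin(a)                 # d(2 cos a)/da per radian
    return sigma_r / (np.deg2rad(alpha_nom_deg) * abs(slope))


class TestIdealEstimator:
    def test_unity_b1_round_trip(self):
        # true = nominal 60 deg: ratio sin120/sin60 = 1 -> arccos(1/2) = 60
        s_a = np.sin(np.deg2rad(60.0))
        s_2a = np.sin(np.deg2rad(120.0))
        assert dam_estimate_ideal(s_a, s_2a, 60.0) == pytest.approx(1.0, rel=1e-12)

    def test_worst_case_b1_round_trip(self):
        # true flip 0.59 * 65 = 38.35 deg
        s_a = np.sin(np.deg2rad(38.35))
        s_2a = np.sin(np.deg2rad(76.7))
        assert dam_estimate_ideal(s_a, s_2a, 65.0) == pytest.approx(0.59, rel=1e-12)
        assert s_2a / s_a == pytest.approx(2 * np.cos(np.deg2rad(38.35)), rel=1e-12)

    def test_ratio_two_gives_zero(self):
        assert dam_estimate_ideal(1.0, 2.0, 65.0) == pytest.approx(0.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dam_estimate_ideal(0.0, 1.0, 65.0)
        with pytest.raises(ValueError):
            dam_estimate_ideal(1.0, 2.5, 65.0)


class TestRatioLUT:
    def test_hard_pulse_values_and_monotonicity(self, hard_pulse):
        lut = build_ratio_lut(hard_pulse, k=2.0)
        idx = np.searchsorted(lut.true_fa_grid_deg, 60.0)
        assert lut.true_fa_grid_deg[idx] == 60.0
        assert lut.ratio_values[idx] == pytest.approx(1.0, rel=1e-10)  # 2 cos 60
        assert np.all(np.diff(lut.ratio_values) < 0)
        assert lut.true_fa_grid_deg[-1] <= 90.0

    def test_inversion_exact_at_nodes(self, hard_pulse):
        lut = build_ratio_lut(hard_pulse, k=2.0)
        fa_back = lut.invert_ratio(lut.ratio_values)
        np.testing.assert_allclose(fa_back, lut.true_fa_grid_deg, atol=1e-10)

    def test_hard_pulse_lut_matches_arccos_formula(self, hard_pulse):
        lut = build_ratio_lut(hard_pulse, k=2.0)
        rng = np.random.default_rng(11)
        for b1 in rng.uniform(0.6, 1.1, size=6):
            a = np.deg2rad(b1 * 65.0)
            ratio = np.sin(2 * a) / np.sin(a)
            est = estimate_b1_lut(ratio, lut, 65.0)
            ideal = dam_estimate_ideal(np.sin(a), np.sin(2 * a), 65.0)
            assert est == pytest.approx(ideal, abs=5e-5)

    def test_slice_profile_round_trip(self, pulse):
        lut = build_ratio_lut(pulse, k=2.0)
        mags = slice_signal_magnitude(pulse, np.array([0.8 * 65.0, 0.8 * 130.0]))
        est = estimate_b1_lut(mags[1] / mags[0], lut, 65.0)
        assert est == pytest.approx(0.8, abs=1e-3)

    def test_out_of_range_ratio_clamps_to_endpoints(self, hard_pulse):
        lut = build_ratio_lut(hard_pulse, k=2.0)
        amb = ambiguity_angle_deg(hard_pulse, 2.0)
        # ratio below the LUT minimum -> largest tabulated FA (ambiguity angle)
        assert estimate_b1_lut(-5.0, lut, 65.0) == pytest.approx(
            lut.true_fa_grid_deg[-1] / 65.0, rel=1e-9)
        assert lut.true_fa_grid_deg[-1] == pytest.approx(amb, abs=1.0)
        # ratio above the maximum -> smallest tabulated FA
        assert estimate_b1_lut(5.0, lut, 65.0) == pytest.approx(
            lut.true_fa_grid_deg[0] / 65.0, rel=1e-9)

    def test_rejects_coarse_grid(self, hard_pulse):
        with pytest.raises(ValueError):
            build_ratio_lut(hard_pulse, k=2.0, fa_step_deg=2.0)


class TestErrorPropagation:
    def test_matches_ideal_closed_form(self):
        got = b1_sd_error_propagation(B1Pair(65.0, 2.0), 0.59, 12.0, "ideal")
        assert got == pytest.approx(ideal_ep_oracle(65.0, 0.59, 12.0), rel=1e-3)
        assert got == pytest.approx(0.1609, abs=5e-4)

    def test_slice_profile_operating_point(self, pulse):
        # regression value for the default pulse at the reference point
        got = b1_sd_error_propagation(B1Pair(65.0, 2.0), 0.59, 12.0, pulse)
        assert got == pytest.approx(0.1584, rel=5e-3)

    def test_infinite_snr_limit(self, pulse):
        got = b1_sd_error_propagation(B1Pair(65.0, 2.0), 0.59, 1e9, pulse)
        assert got == pytest.approx(0.0, abs=1e-6)

    def test_sd_decreases_with_b1(self, pulse):
        sds = [b1_sd_error_propagation(B1Pair(65.0, 2.0), b1, 12.0, pulse)
               for b1 in (0.59, 0.8, 1.0, 1.14)]
        assert np.all(np.diff(sds) < 0)

    def test_rejects_b1_beyond_invertible_range(self, pulse):
        with pytest.raises(ValueError):
            b1_sd_error_propagation(B1Pair(65.0, 2.0), 1.6, 12.0, pulse)


class TestMonteCarlo:
    def test_zero_noise_gives_zero_sd(self, pulse):
        sd = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.8, np.inf, 200, 0, pulse)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_seed_reproducibility(self, pulse):
        a = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.8, 12.0, 2000, 5, pulse)
        b = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.8, 12.0, 2000, 5, pulse)
        assert a == b

    def test_agrees_with_error_propagation_in_linear_regime(self, pulse):
        # at low noise the delta method is accurate, so the MC SD must
        # match error propagation within Monte-Carlo uncertainty
        n = 10_000
        mc = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.59, 100.0, n, 2, pulse)
        ep = b1_sd_error_propagation(B1Pair(65.0, 2.0), 0.59, 100.0, pulse)
        se = ep / np.sqrt(2 * (n - 1))
        assert abs(mc - ep) < 3 * se

    def test_discard_vs_clamp_bias(self, pulse):
        # clamping non-invertible ratios piles huge negative outliers at the
        # low-FA endpoint; discarding keeps the estimator's bias small
        _, det_d = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.59, 12.0, 4000, 7,
                                     pulse, on_invalid="discard",
                                     return_details=True)
        sd_c, det_c = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.59, 12.0, 4000, 7,
                                        pulse, on_invalid="clamp",
                                        return_details=True)
        sd_d = b1_sd_monte_carlo(B1Pair(65.0, 2.0), 0.59, 12.0, 4000, 7, pulse)
        assert abs(det_d["mean_deviation"]) < 0.02
        assert abs(det_c["mean_deviation"]) > 0.03
        assert sd_c > sd_d


class TestPairSearch:
    def test_toy_grid_matches_enumeration(self):
        b1_grid = np.array([0.7, 0.9, 1.1])
        alphas = [40.0, 65.0, 80.0]  # all feasible: 1.1 * 80 < 90 deg
        pair, worst = optimal_b1_pair(b1_grid, [2.0], 12.0, alphas,
                                      fa_max_deg=200.0, signal_model="ideal")
        expected = min(
            (max(b1_sd_error_propagation(B1Pair(a, 2.0), b1, 12.0, "ideal")
                 for b1 in b1_grid), a)
            for a in alphas)
        assert pair.alpha_deg == expected[1]
        assert worst == pytest.approx(expected[0], rel=1e-6)

    def test_liver_search_selects_65_130(self, pulse):
        pair, worst = optimal_b1_pair(
            np.round(np.arange(0.59, 1.1501, 0.05), 6),
            [1.5, 2.0, 2.5, 3.0], 12.0, np.arange(5.0, 361.0, 5.0),
            fa_max_deg=130.0, signal_model=pulse)
        assert (pair.alpha_deg, pair.k) == (65.0, 2.0)
        # worst case sits at the lowest B1+ factor on the grid
        assert worst == pytest.approx(
            b1_sd_error_propagation(B1Pair(65.0, 2.0), 0.59, 12.0, pulse),
            rel=1e-3)

    def test_empty_feasible_set_raises(self):
        with pytest.raises(ValueError):
            optimal_b1_pair([1.0], [2.0], 12.0, [100.0], fa_max_deg=130.0,
                            signal_model="ideal")
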