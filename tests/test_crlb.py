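"""Fisher information, total noise variance, worst-case COV, pooled variance."""

import numpy as np
import pytest

import vfadesign as vd
from vfadesign.crlb import (
    ParamSpace,
    fisher_matrix,
    pooled_weighted_variance,
    t1_cov_percent,
    total_noise_variance,
    worst_case_cov,
)
from vfadesign.spgr_model import NoiseSpec, SPGRSettings, TissueParams, spgr_signal


class TestTotalNoiseVariance:
    def test_reduces_to_spgr_noise_without_b1_noise(self):
        noise = NoiseSpec(12.48, 0.0)
        got = total_noise_variance(15.0, 0.9, 800, 5000, 4.1, noise)
        assert got == pytest.approx(12.48**2, rel=1e-12)

    def test_b1_term_vanishes_at_ernst_angle(self):
        # choose the nominal FA whose true flip lands on the Ernst angle
        b1 = 0.9
        nominal = vd.ernst_angle_deg(4.1, 800) / b1
        noise = NoiseSpec(10.0, 0.046)
        got = total_noise_variance(nominal, b1, 800, 5000, 4.1, noise)
        assert got == pytest.approx(100.0, rel=1e-9)

    def test_matches_monte_carlo_propagation(self):
        # MC oracle: variance of S(alpha_nom * (b1 + eps)) for eps ~ N(0, s^2)
        fa_nom, b1, t1, m0, tr, sigma_b1 = 15.0, 0.9, 800.0, 5000.0, 4.1, 0.046
        rng = np.random.default_rng(42)
        eps = sigma_b1 * rng.standard_normal(1_000_000)
        samples = spgr_signal(fa_nom * (b1 + eps), tr, t1, m0)
        mc_var = samples.var(ddof=1)
        pred = total_noise_variance(fa_nom, b1, t1, m0, tr,
                                    NoiseSpec(0.0, sigma_b1))
        assert pred == pytest.approx(mc_var, rel=0.02)


class TestFisherMatrix:
    SCHEME = SPGRSettings(4.1, 5000, (2.0, 3.0, 15.0, 15.0))
    TISSUE = TissueParams(700, 0.59)
    NOISE = NoiseSpec(12.480166442424476, 0.046)  # SNR 12.5 reference

    def test_single_flip_angle_is_singular(self):
        res = fisher_matrix(SPGRSettings(4.1, 5000, (10.0,)), self.TISSUE,
                            self.NOISE)
        assert res.singular
        assert np.isinf(res.t1_variance)

    def test_identical_repeated_angles_are_singular(self):
        res = fisher_matrix(SPGRSettings(4.1, 5000, (10.0, 10.0, 10.0)),
                            self.TISSUE, self.NOISE)
        assert res.singular

    def test_duplication_halves_variance(self):
        doubled = SPGRSettings(4.1, 5000, self.SCHEME.nominal_fas_deg * 2)
        one = fisher_matrix(self.SCHEME, self.TISSUE, self.NOISE)
        two = fisher_matrix(doubled, self.TISSUE, self.NOISE)
        np.testing.assert_allclose(two.matrix, 2 * one.matrix, rtol=1e-12)
        assert two.t1_variance == pytest.approx(one.t1_variance / 2, rel=1e-12)
        assert two.t1_cov_percent == pytest.approx(
            one.t1_cov_percent / np.sqrt(2), rel=1e-12)

    def test_symmetric_positive_semidefinite(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            fas = tuple(rng.uniform(1, 20, size=3))
            tissue = TissueParams(rng.uniform(400, 2000), rng.uniform(0.6, 1.2))
            res = fisher_matrix(SPGRSettings(4.1, 5000, fas), tissue, self.NOISE)
            assert res.matrix[0, 1] == res.matrix[1, 0]
            eig = np.linalg.eigvalsh(res.matrix)
            assert np.all(eig >= -1e-9 * np.trace(res.matrix))

    def test_adding_a_measurement_never_hurts(self):
        base = fisher_matrix(self.SCHEME, self.TISSUE, self.NOISE)
        for extra in (2.0, 7.0, 15.0):
            bigger = SPGRSettings(4.1, 5000,
                                  self.SCHEME.nominal_fas_deg + (extra,))
            res = fisher_matrix(bigger, self.TISSUE, self.NOISE)
            assert res.t1_variance <= base.t1_variance + 1e-12


class TestT1Cov:
    def test_worst_case_operating_point(self):
        # 4 optimal FAs at SNR 12.5, sigma_B1 = 0.046, worst grid corner
        scheme = SPGRSettings(4.1, 5000, (2.0, 3.0, 15.0, 15.0))
        noise = NoiseSpec(vd.sigma_from_snr(12.5), 0.046)
        cov = t1_cov_percent(scheme, TissueParams(700, 0.59), noise)
        assert cov == pytest.approx(15.70, abs=0.05)

    def test_linear_scaling_without_b1_noise(self):
        scheme = SPGRSettings(4.1, 5000, (2.0, 15.0))
        tissue = TissueParams(800, 1.0)
        c1 = t1_cov_percent(scheme, tissue, NoiseSpec(5.0, 0.0))
        c3 = t1_cov_percent(scheme, tissue, NoiseSpec(15.0, 0.0))
        assert c3 == pytest.approx(3 * c1, rel=1e-9)

    def test_monotone_in_snr(self):
        scheme = SPGRSettings(4.1, 5000, (2.0, 2.0, 15.0, 15.0))
        tissue = TissueParams(900, 0.84)
        covs = [t1_cov_percent(scheme, tissue,
                               NoiseSpec(vd.sigma_from_snr(snr), 0.046))
                for snr in (12.5, 25, 50)]
        assert covs[0] > covs[1] > covs[2]


class TestWorstCase:
    def test_single_point_grid(self):
        scheme = SPGRSettings(4.1, 5000, (2.0, 15.0))
        noise = NoiseSpec(10.0, 0.046)
        space = ParamSpace((800.0,), (0.9,))
        cov, t1, b1 = worst_case_cov(scheme, space, noise)
        assert (t1, b1) == (800.0, 0.9)
        assert cov == pytest.approx(
            t1_cov_percent(scheme, TissueParams(800, 0.9), noise), rel=1e-12)

    def test_subgrid_bounded_by_full_grid(self, liver_space):
        scheme = SPGRSettings(4.1, 5000, (2.0, 3.0, 15.0, 15.0))
        noise = NoiseSpec(vd.sigma_from_snr(12.5), 0.046)
        sub = ParamSpace(liver_space.t1_grid_ms[2:4], liver_space.b1_grid[3:8])
        assert (worst_case_cov(scheme, sub, noise)[0]
                <= worst_case_cov(scheme, liver_space, noise)[0])

    def test_liver_worst_case_at_low_t1_low_b1(self, liver_space):
        scheme = SPGRSettings(4.1, 5000, (2.0, 3.0, 15.0, 15.0))
        noise = NoiseSpec(vd.sigma_from_snr(12.5), 0.046)
        _, t1, b1 = worst_case_cov(scheme, liver_space, noise)
        assert (t1, b1) == (700.0, 0.59)


class TestPooledVariance:
    def test_single_roi_returns_own_variance(self):
        assert pooled_weighted_variance([850.0], [123.0], [2.0]) == 123.0

    def test_identical_rois(self):
        assert pooled_weighted_variance([800, 800, 800], [50, 50, 50],
                                        [1, 1, 1]) == pytest.approx(50.0)

    def test_two_roi_hand_computation(self):
        # 0.5*(100 + 2500) + 0.5*(400 + 2500) = 2750
        got = pooled_weighted_variance([800.0, 900.0], [100.0, 400.0],
                                       [0.5, 0.5])
        assert got == pytest.approx(2750.0, rel=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pooled_weighted_variance([], [], [])


class TestParamSpace:
    def test_liver_defaults(self, liver_space):
        assert liver_space.t1_grid_ms == tuple(np.arange(700.0, 1201.0, 100.0))
        assert liver_space.b1_grid[0] == 0.59
        assert liver_space.b1_grid[-1] == 1.14
        assert len(liver_space.b1_grid) == 12

    def test_validation(self):
        with pytest.raises(ValueError):
            ParamSpace((), (0.9,))
        with pytest.raises(ValueError):
            ParamSpace((800.0, 700.0), (0.9,))
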