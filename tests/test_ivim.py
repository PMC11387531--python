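"""IVIM forward model and voxel-wise estimators."""

import math

import numpy as np
import pytest

from prmivim.ivim import (
    BValueScheme,
    GridSamplerSettings,
    IvimPriors,
    fit_signals,
    fit_volume,
    fit_voxel_bayesian,
    fit_voxel_lsq,
    ivim_signal,
)
from prmivim.phantom import make_phantom, simulate_dwi

from conftest import TRUE_D, TRUE_DSTAR, TRUE_F, TRUE_S0


def closed_form(b, S0, D, f, Ds):
    """Independent scalar evaluation of the bi-exponential model."""
    return S0 * (f * math.exp(-b * Ds) + (1.0 - f) * math.exp(-b * D))


class TestForwardModel:
    def test_b0_returns_s0_exactly(self):
        assert ivim_signal(0.0, 123.4, 1e-3, 0.2, 1e-2) == 123.4

    def test_f0_collapses_to_monoexponential(self):
        b = np.array([0.0, 100.0, 800.0])
        out = ivim_signal(b, 500.0, 1.2e-3, 0.0, 2e-2)
        np.testing.assert_allclose(out, 500.0 * np.exp(-b * 1.2e-3), rtol=1e-15)

    def test_table1_mean_parameters_at_b800(self):
        # frozen from an independent scalar evaluation of the closed form
        val = ivim_signal(800.0, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        assert val == pytest.approx(370.9033468436466, rel=1e-12)
        assert val == pytest.approx(371.0, abs=0.5)

    def test_matches_independent_evaluation_on_random_draws(self, priors):
        rng = np.random.default_rng(0)
        n = 1000
        S0 = rng.uniform(10.0, 2000.0, n)
        D = rng.uniform(*priors.D_bounds, n)
        f = rng.uniform(*priors.f_bounds, n)
        Ds = rng.uniform(*priors.Dstar_bounds, n)
        b = rng.uniform(0.0, 1000.0, n)
        ours = ivim_signal(b, S0, D, f, Ds)
        oracle = np.array([closed_form(*args) for args in zip(b, S0, D, f, Ds)])
        np.testing.assert_allclose(ours, oracle, rtol=1e-12)

    def test_monotone_decreasing_and_bounded(self, scheme):
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        assert np.all(np.diff(sig) < 0)
        assert sig[0] == TRUE_S0
        assert np.all((0 <= sig) & (sig <= TRUE_S0))

    def test_negative_b_rejected(self):
        with pytest.raises(ValueError):
            ivim_signal(-1.0, 1.0, 1e-3, 0.1, 1e-2)


class TestScheme:
    @pytest.mark.parametrize(
        "bvals",
        [
            (10.0, 100.0, 500.0, 800.0),  # no b=0
            (0.0, 100.0, 100.0, 800.0),  # not strictly increasing
            (0.0, 100.0, 800.0),  # too short
            (0.0, -5.0, 100.0, 800.0),  # negative
        ],
    )
    def test_invalid_schemes_rejected(self, bvals):
        with pytest.raises(ValueError):
            BValueScheme(bvals)

    def test_perfusion_identifiability_flag(self):
        assert BValueScheme((0.0, 20.0, 200.0, 800.0)).perfusion_identifiable
        assert not BValueScheme((0.0, 300.0, 500.0, 800.0)).perfusion_identifiable


class TestLsqFitter:
    def test_noiseless_recovery_within_one_percent(self, scheme):
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        est = fit_voxel_lsq(sig, scheme)
        assert est.D == pytest.approx(TRUE_D, rel=0.01)
        assert est.f == pytest.approx(TRUE_F, rel=0.01)
        assert est.Dstar == pytest.approx(TRUE_DSTAR, rel=0.01)
        assert est.flag == "ok"

    def test_monoexponential_limit(self, scheme):
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, 0.0, TRUE_DSTAR)
        est = fit_voxel_lsq(sig, scheme)
        assert est.f < 0.01
        assert est.D == pytest.approx(TRUE_D, rel=0.005)

    def test_constant_signal_clips_to_lower_bound(self, scheme, priors):
        est = fit_voxel_lsq(np.full(len(scheme), 800.0), scheme)
        assert est.D == pytest.approx(priors.D_bounds[0], rel=1e-6)
        assert est.flag == "clipped"

    def test_nonfinite_signal_flags_failure_without_raising(self, scheme):
        sig = np.full(len(scheme), np.nan)
        est = fit_voxel_lsq(sig, scheme)
        assert est.flag == "failed"


class TestBayesianFitter:
    def test_noiseless_posterior_mean_near_truth(self, scheme):
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        est = fit_voxel_bayesian(sig, scheme)
        assert est.D == pytest.approx(TRUE_D, rel=0.02)
        assert est.f == pytest.approx(TRUE_F, rel=0.02)
        assert est.Dstar == pytest.approx(TRUE_DSTAR, rel=0.02)
        assert est.S0 == pytest.approx(TRUE_S0, rel=0.02)

    def test_same_seed_identical_estimates(self, scheme):
        rng = np.random.default_rng(3)
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        noisy = np.sqrt((sig + rng.normal(0, 20, sig.shape)) ** 2
                        + rng.normal(0, 20, sig.shape) ** 2)
        e1 = fit_voxel_bayesian(noisy, scheme, seed=7)
        e2 = fit_voxel_bayesian(noisy, scheme, seed=7)
        assert (e1.D, e1.f, e1.Dstar, e1.S0) == (e2.D, e2.f, e2.Dstar, e2.S0)

    def test_order_invariance(self, scheme):
        """Jointly permuting (b, signal) pairs leaves estimates unchanged."""
        rng = np.random.default_rng(5)
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        noisy = np.sqrt((sig + rng.normal(0, 20, sig.shape)) ** 2
                        + rng.normal(0, 20, sig.shape) ** 2)
        perm = rng.permutation(len(scheme))
        b_perm = scheme.array[perm]
        order = np.argsort(b_perm)
        scheme_perm = BValueScheme(tuple(b_perm[order]))
        e1 = fit_voxel_bayesian(noisy, scheme)
        e2 = fit_voxel_bayesian(noisy[perm][order], scheme_perm)
        assert e1.D == pytest.approx(e2.D, rel=1e-12)
        assert e1.Dstar == pytest.approx(e2.Dstar, rel=1e-12)

    def test_sigma_ladder_consistency(self, scheme):
        """Posterior mean approaches the truth as the noise level drops."""
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        errs = []
        for sigma, seed in ((40.0, 0), (5.0, 0), (0.0, 0)):
            rng = np.random.default_rng(seed)
            noisy = (
                np.sqrt((sig + rng.normal(0, sigma, sig.shape)) ** 2
                        + rng.normal(0, sigma, sig.shape) ** 2)
                if sigma > 0 else sig
            )
            est = fit_voxel_bayesian(noisy, scheme)
            errs.append(abs(est.D - TRUE_D) / TRUE_D)
        assert errs[2] < 0.02
        assert errs[2] <= errs[1] <= errs[0] + 0.02

    def test_high_b_only_scheme_flagged_unidentifiable(self):
        scheme = BValueScheme((0.0, 300.0, 500.0, 800.0))
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        est = fit_voxel_bayesian(sig, scheme)
        assert est.flag == "unidentifiable"

    def test_batch_recovery_bounds_at_snr50(self, scheme):
        """Median relative bias on 500 Rician replicate voxels at SNR 50."""
        rng = np.random.default_rng(2024)
        sig = ivim_signal(scheme.array, TRUE_S0, TRUE_D, TRUE_F, TRUE_DSTAR)
        sigma = TRUE_S0 / 50.0
        noisy = np.sqrt(
            (sig + rng.normal(0, sigma, (500, len(scheme)))) ** 2
            + rng.normal(0, sigma, (500, len(scheme))) ** 2
        )
        theta, _, _ = fit_signals(noisy, scheme)
        bias = np.median((theta[:, 1:] - [TRUE_D, TRUE_F, TRUE_DSTAR])
                         / [TRUE_D, TRUE_F, TRUE_DSTAR], axis=0)
        assert abs(bias[0]) <= 0.05  # D
        assert abs(bias[1]) <= 0.15  # f
        assert abs(bias[2]) <= 0.30  # D*


class TestFitVolume:
    @pytest.fixture(scope="class")
    def tiny_phantom(self):
        return make_phantom(grid_shape=(24, 24, 24), voxel_size=(3.0, 3.0, 3.0),
                            tumor_radii_mm=(14.0, 12.0, 12.0), seed=9)

    def test_maps_defined_exactly_on_mask(self, tiny_phantom, scheme):
        dwi = simulate_dwi(tiny_phantom, sigma=0.0)
        mask = np.zeros(tiny_phantom.grid.shape, dtype=bool)
        vox = np.argwhere(tiny_phantom.gtv_mask)[:10]
        mask[tuple(vox.T)] = True
        maps = fit_volume(dwi, mask, method="bayesian")
        assert maps.fit_mask.sum() == 10
        assert np.isfinite(maps.D_map[mask]).all()
        assert np.isnan(maps.D_map[~mask]).all()

    def test_lsq_and_bayesian_agree_on_noiseless_phantom(self, tiny_phantom):
        dwi = simulate_dwi(tiny_phantom, sigma=0.0)
        mask = tiny_phantom.gtv_mask
        lsq = fit_volume(dwi, mask, method="lsq")
        bay = fit_volume(dwi, mask, method="bayesian")
        for a, b in ((lsq.D_map, bay.D_map), (lsq.f_map, bay.f_map),
                     (lsq.Dstar_map, bay.Dstar_map)):
            rel = np.abs(a[mask] - b[mask]) / np.maximum(np.abs(a[mask]), 1e-12)
            assert np.nanmax(rel) < 0.02

    def test_masked_mean_recovery_at_snr50(self, tiny_phantom):
        dwi = simulate_dwi(tiny_phantom, sigma=TRUE_S0 / 50.0, seed=4)
        mask = tiny_phantom.gtv_mask
        maps = fit_volume(dwi, mask, method="bayesian")
        est_mean = np.nanmean(maps.D_map[mask])
        true_mean = tiny_phantom.true_D[mask].mean()
        assert est_mean == pytest.approx(true_mean, rel=0.05)

    def test_empty_mask_rejected(self, tiny_phantom):
        dwi = simulate_dwi(tiny_phantom, sigma=0.0)
        with pytest.raises(ValueError, match="empty"):
            fit_volume(dwi, np.zeros(tiny_phantom.grid.shape, dtype=bool))
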