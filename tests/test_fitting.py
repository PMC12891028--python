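import numpy as np
import pytest
from dataclasses import replace

from thickfil.fitting import (
    CalibrationError,
    FitTarget,
    FreeParamSpec,
    calibrate_baseline,
    calibration_profile,
    hill_curve,
    make_log_posterior,
    model_curve_for_target,
    model_pca50,
    reconstruct_experimental_targets,
    run_ensemble_mcmc,
    sum_squared_residuals,
)
from thickfil.sarcomere import KineticParams, ModelVariant


class TestTargets:
    def test_reconstructed_targets_encode_printed_shifts(self):
        targets = reconstruct_experimental_targets(
            pCa_grid=np.linspace(6.4, 4.8, 161)
        )
        assert len(targets) == 4
        by_cond = {(t.sl_um, t.phosphorylated): t for t in targets}
        # curve midpoints differ by the printed shifts
        for (sl, shift) in ((1.9, 0.08), (2.3, 0.12)):
            u = by_cond[(sl, False)]
            p = by_cond[(sl, True)]
            # pCa at half force via interpolation
            f_u = np.interp(0.5, u.force_norm, u.pCa)
            f_p = np.interp(0.5, p.force_norm, p.pCa)
            assert f_p - f_u == pytest.approx(shift, abs=0.01)

    def test_target_validation(self):
        with pytest.raises(ValueError):
            FitTarget(1.9, False, [5.5, 5.6], [0.5, 1.5])


class TestLikelihood:
    def test_perfect_model_only_prior_remains(self, geom, variants):
        spec = FreeParamSpec()
        grid = np.linspace(6.2, 5.0, 6)
        curve = hill_curve(grid, 5.56, 4.0)
        t = FitTarget(1.9, False, grid, curve)
        log_post = make_log_posterior(geom, variants["A"], [t], spec,
                                      base_params=KineticParams())

        # model == data case emulated through sigma -> infinity
        t_wide = FitTarget(1.9, False, grid, curve, sigma=1e9)
        lp_wide = make_log_posterior(geom, variants["A"], [t_wide], spec,
                                     base_params=KineticParams())
        theta = np.array([2.0, 0.004])
        prior = -float(np.sum(np.log(theta)))
        assert lp_wide(theta) == pytest.approx(prior, abs=1e-6)
        assert log_post(theta) <= lp_wide(theta)

    def test_wider_sigma_raises_likelihood_of_misfit(self, geom, variants):
        spec = FreeParamSpec()
        theta = np.array([2.0, 0.004])
        lps = []
        for sigma in (0.02, 0.04):
            t = FitTarget(1.9, False, np.linspace(6.2, 5.0, 5),
                          hill_curve(np.linspace(6.2, 5.0, 5), 5.56, 4.0),
                          sigma=sigma)
            lps.append(make_log_posterior(geom, variants["A"], [t], spec,
                                          base_params=KineticParams())(theta))
        assert lps[1] > lps[0]

    def test_out_of_bounds_is_minus_infinity(self, geom, variants):
        spec = FreeParamSpec()
        lp = make_log_posterior(geom, variants["A"],
                                reconstruct_experimental_targets()[:1], spec,
                                base_params=KineticParams())
        assert lp(np.array([0.5, 0.004])) == -np.inf
        assert lp(np.array([2.0, 1.0])) == -np.inf


class TestMCMC:
    def test_quadratic_posterior_recovers_analytic_mean(self):
        """Single free parameter with a Gaussian log-posterior centred at 2."""
        def log_post(x):
            return -0.5 * ((x[0] - 2.0) / 0.25) ** 2

        post = run_ensemble_mcmc(log_post, [1.5], n_walkers=10, n_steps=400,
                                 burn_in=100, seed=3, param_names=("x",))
        samples = post.flat[:, 0]
        se = samples.std() / np.sqrt(len(samples) / 50)  # crude ESS guess
        assert abs(samples.mean() - 2.0) < max(3 * se, 0.05)
        assert abs(samples.std() - 0.25) < 0.05

    def test_same_seed_identical_chains(self):
        def log_post(x):
            return -0.5 * float(np.sum(x**2))

        a = run_ensemble_mcmc(log_post, [1.0, 1.0], n_walkers=8, n_steps=50,
                              burn_in=10, seed=9, param_names=("a", "b"))
        b = run_ensemble_mcmc(log_post, [1.0, 1.0], n_walkers=8, n_steps=50,
                              burn_in=10, seed=9, param_names=("a", "b"))
        assert np.array_equal(a.chain, b.chain)

    def test_walker_count_validated(self):
        with pytest.raises(ValueError):
            run_ensemble_mcmc(lambda x: 0.0, [1.0, 1.0], n_walkers=2)

    def test_posterior_width_shrinks_with_noise(self):
        """Tighter observation noise -> narrower posterior."""
        def make(sigma):
            def log_post(x):
                return -0.5 * ((x[0] - 2.0) / sigma) ** 2
            return log_post

        widths = []
        for sigma in (0.5, 0.1):
            post = run_ensemble_mcmc(make(sigma), [2.0], n_walkers=10,
                                     n_steps=300, burn_in=100, seed=5,
                                     param_names=("x",))
            widths.append(post.flat[:, 0].std())
        assert widths[1] < widths[0]


class TestCalibration:
    def test_calibrated_baseline_hits_operating_points(self, geom, variants):
        cal = calibrate_baseline(geom, KineticParams())
        p19 = model_pca50(geom, cal, variants["none"], "none", 1.9).pCa50
        p23 = model_pca50(geom, cal, variants["none"], "none", 2.3).pCa50
        assert p19 == pytest.approx(5.56, abs=0.005)
        assert p23 == pytest.approx(5.64, abs=0.005)

    def test_calibration_idempotent(self, geom):
        cal = calibrate_baseline(geom, KineticParams())
        cal2 = calibrate_baseline(geom, cal)
        assert cal2.a_kon == pytest.approx(cal.a_kon, rel=1e-3)
        assert cal2.passive_gain == pytest.approx(cal.passive_gain, rel=1e-2)

    def test_unreachable_operating_point_raises(self, geom):
        # a long-SL pCa50 below the short-SL one needs negative passive
        # force, which the titin term cannot produce
        with pytest.raises(CalibrationError):
            calibrate_baseline(geom, KineticParams(), pca50_short=5.56,
                               pca50_long=5.0)

    def test_profile_pins_baseline_across_k_force(self, geom, variants):
        lookup = calibration_profile(geom, KineticParams(), [0.003, 0.005])
        for kf in (0.003, 0.004, 0.005):
            par = lookup(kf)
            p19 = model_pca50(geom, par, variants["none"], "none", 1.9).pCa50
            assert p19 == pytest.approx(5.56, abs=0.02)
        with pytest.raises(ValueError):
            lookup(0.05)


class TestRecovery:
    def test_synthetic_phi_recovery_grid_scan(self, geom, variants):
        """Targets generated at phi_P = 3 put the likelihood maximum near 3
        on a 1D grid scan (independent of the sampler)."""
        truth = replace(KineticParams(), phi_P=3.0)
        targets = []
        for sl in (1.9, 2.3):
            for phos in (False, True):
                v = variants["A"] if phos else variants["none"]
                t = FitTarget(sl, phos, np.linspace(6.4, 4.8, 9), np.zeros(9))
                curve = model_curve_for_target(geom, truth, v, t)
                targets.append(FitTarget(sl, phos, t.pCa, np.clip(curve, 0, 1.1)))
        spec = FreeParamSpec(names=("phi_P",), lower=(1.0,), upper=(10.0,))
        lp = make_log_posterior(geom, variants["A"], targets, spec,
                                base_params=KineticParams())
        phis = np.linspace(1.5, 6.0, 19)
        vals = [lp(np.array([p])) for p in phis]
        assert phis[int(np.argmax(vals))] == pytest.approx(3.0, abs=0.25)

    def test_variant_substitution_inflates_residual(self, geom, variants):
        par = replace(calibrate_baseline(geom, KineticParams()), phi_P=3.0)
        targets = reconstruct_experimental_targets()
        ssr_a = sum_squared_residuals(geom, par, variants["A"], targets)
        ssr_b = sum_squared_residuals(geom, par, variants["B"], targets)
        ssr_c = sum_squared_residuals(geom, par, variants["C"], targets)
        assert ssr_b > ssr_a
        assert ssr_c > ssr_a
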