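import numpy as np
import pytest
from dataclasses import replace

from thickfil.sarcomere import (
    HeadClasses,
    KineticParams,
    ModelVariant,
    SimProtocol,
    SimulationError,
    fit_hill,
    force_pca_curve,
    head_rates,
    ktr_protocol,
    mean_field_simulate,
    run_simulation,
    steady_state_force,
    thin_activation_ss,
)


class TestHeadRates:
    def test_zero_force_removes_phospho_effect(self, params, variants):
        r_p = head_rates("OFF", "C", "blocked", 0.0, 1.0, params,
                         variants["A"], phosphorylated=True)
        r_u = head_rates("OFF", "C", "blocked", 0.0, 1.0, params,
                         variants["A"], phosphorylated=False)
        assert r_p["ON"] == r_u["ON"] == params.k1_0

    def test_model_a_spares_free_head(self, params, variants):
        F = 100.0
        free = head_rates("OFF", "C", "free", F, 1.0, params, variants["A"], True)
        blocked = head_rates("OFF", "C", "blocked", F, 1.0, params, variants["A"], True)
        base = head_rates("OFF", "C", "free", F, 1.0, params, variants["A"], False)
        assert free["ON"] == base["ON"]
        assert blocked["ON"] > base["ON"]

    def test_model_c_boosts_both_heads_in_c_zone(self, params, variants):
        F = 100.0
        for role in ("blocked", "free"):
            r = head_rates("OFF", "C", role, F, 1.0, params, variants["C"], True)
            expected = params.k1_0 * (1 + params.phi_P * params.k_force * F)
            assert r["ON"] == pytest.approx(expected)

    def test_model_b_targets_all_zones_blocked_only(self, params, variants):
        F = 50.0
        for zone in ("P", "C", "D"):
            rb = head_rates("OFF", zone, "blocked", F, 1.0, params, variants["B"], True)
            rf = head_rates("OFF", zone, "free", F, 1.0, params, variants["B"], True)
            assert rb["ON"] > rf["ON"]


class TestMeanField:
    def test_zero_calcium_gives_no_force(self, geom, params, variants):
        F = steady_state_force(geom, params, variants["none"], "none", 1.9, 9.0)
        assert F < 1e-3 * params.f_head * geom.n_heads_half

    def test_no_mechanosensing_matches_linear_fixed_point(self, geom, variants):
        """With k_force = 0 the 3-state balance is closed-form."""
        par = KineticParams(k_force=0.0, a_kon=1e4, a_koff=1e-6, a_coop=0.0,
                            passive_gain=0.0)
        F = steady_state_force(geom, par, variants["none"], "none", 1.9, 4.5)
        k3a = par.k3 * 1.0  # a = 1, full overlap
        on = par.k1_0 / (par.k1_0 * (1 + k3a / par.k4) + par.k2)
        fg = k3a * on / par.k4
        assert F == pytest.approx(geom.n_heads_half * par.f_head * fg, rel=1e-6)

    def test_ode_occupancies_conserved_and_match_fixed_point(
        self, geom, params, variants
    ):
        res = mean_field_simulate(geom, params, variants["none"], "none",
                                  SimProtocol(pCa=4.5, duration_s=4.0))
        for occ in res.occupancy.values():
            assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-6)
        ss = steady_state_force(geom, params, variants["none"], "none", 1.9, 4.5)
        assert res.force_pN[-1] == pytest.approx(ss, rel=1e-3)

    def test_steady_state_independent_of_initialization(self, geom, params, variants):
        proto = SimProtocol(pCa=5.0, duration_s=6.0)
        hc = HeadClasses.build(geom, variants["none"], "none")
        n = len(hc.keys)
        y_on = np.zeros(1 + 2 * n)
        y_on[1:1 + n] = 1.0  # start all ON instead of all OFF
        r0 = mean_field_simulate(geom, params, variants["none"], "none", proto)
        r1 = mean_field_simulate(geom, params, variants["none"], "none", proto,
                                 y0=y_on)
        assert r0.force_pN[-1] == pytest.approx(r1.force_pN[-1], abs=1e-4 * max(r0.force_pN[-1], 1))

    def test_force_monotone_in_calcium(self, geom, params, variants):
        forces = [steady_state_force(geom, params, variants["none"], "none", 1.9, p)
                  for p in np.linspace(7.0, 4.5, 11)]
        assert np.all(np.diff(forces) >= -1e-9)

    def test_phi_one_reduces_all_variants_to_baseline(self, geom, variants):
        par = replace(KineticParams(), phi_P=1.0)
        ref = None
        for name in ("none", "A", "B", "C"):
            F = steady_state_force(geom, par, variants[name], "all", 1.9, 5.6)
            ref = F if ref is None else ref
            assert F == pytest.approx(ref, abs=1e-9)

    def test_pca50_nondecreasing_in_phi_for_model_a(self, geom, variants):
        grid = np.linspace(6.6, 4.8, 9)
        p50s = []
        for phi in (1.0, 2.0, 4.0):
            par = replace(KineticParams(), phi_P=phi)
            fit, _, _ = force_pca_curve(geom, par, variants["A"], "all", 1.9, grid)
            p50s.append(fit.pCa50)
        assert np.all(np.diff(p50s) >= -1e-6)

    def test_empty_zone_contributes_no_force(self, variants):
        from thickfil.geometry import build_half_filament

        g = build_half_filament({"zone_counts": {"P": 0, "C": 49, "D": 0}})
        hc = HeadClasses.build(g, variants["none"], "none")
        assert all(k[0] == "C" for k in hc.keys)

    def test_thin_activation_closed_form(self, params):
        a = thin_activation_ss(10.0, params)
        b = params.a_kon * 10.0
        lhs = b * (1 + 2 * params.a_coop * a) * (1 - a)
        assert lhs == pytest.approx(params.a_koff * a, rel=1e-9)


class TestMonteCarlo:
    def test_same_seed_identical_trajectories(self, geom, params, variants):
        proto = SimProtocol(pCa=5.6, duration_s=0.5, seed=11)
        r1 = run_simulation(geom, params, variants["A"], "all", proto)
        r2 = run_simulation(geom, params, variants["A"], "all", proto)
        assert np.array_equal(r1.force_pN, r2.force_pN)

    def test_relaxed_filament_produces_no_force(self, geom, params, variants):
        res = run_simulation(geom, params, variants["none"], "none",
                             SimProtocol(pCa=9.0, duration_s=1.0, seed=1))
        tail = res.force_pN[int(0.5 * res.force_pN.size):]
        assert tail.mean() < 0.01 * params.f_head * geom.n_heads_half
        occ = res.mean_occupancy()
        assert occ[-1, 2] < 0.01  # FG occupancy under 1%

    def test_matches_mean_field_at_saturating_calcium(self, geom, params, variants):
        """MC mean within 5% of the deterministic fixed point (8 replicates)."""
        ss = steady_state_force(geom, params, variants["none"], "none", 1.9, 4.5)
        means = []
        for seed in range(8):
            r = run_simulation(geom, params, variants["none"], "none",
                               SimProtocol(pCa=4.5, duration_s=3.0, seed=seed))
            means.append(r.force_pN[int(0.8 * r.force_pN.size):].mean())
        assert abs(np.mean(means) - ss) / ss < 0.05

    def test_dt_guard(self, geom, params, variants):
        with pytest.raises(SimulationError):
            run_simulation(geom, params, variants["none"], "none",
                           SimProtocol(pCa=4.5, duration_s=0.1, dt_s=0.05, seed=0))


class TestProtocols:
    def test_hill_fit_self_consistency(self):
        grid = np.linspace(6.5, 4.8, 10)
        truth = 1.0 / (1.0 + 10.0 ** (4.0 * (grid - 5.6)))
        fit = fit_hill(grid, truth)
        assert fit.pCa50 == pytest.approx(5.6, abs=1e-6)
        assert fit.n_H == pytest.approx(4.0, rel=1e-6)

    def test_force_scale_invariance_of_hill_params(self, geom, params, variants):
        grid = np.linspace(6.6, 4.8, 9)
        fit1, _, F = force_pca_curve(geom, params, variants["none"], "none", 1.9, grid)
        fit2 = fit_hill(grid, 2.0 * F)
        assert fit2.pCa50 == pytest.approx(fit1.pCa50, abs=1e-9)
        assert fit2.n_H == pytest.approx(fit1.n_H, rel=1e-6)

    def test_two_state_surrogate_ktr_is_f_plus_g(self, geom, variants):
        """Only ON<->FG active: redevelopment rate equals k3 + k4."""
        par = KineticParams(k1_0=1e4, k_force=0.0, k2=0.0, k3=20.0, k4=10.0,
                            a_kon=1e4, a_koff=1e-6, a_coop=0.0, passive_gain=0.0)
        proto = SimProtocol(pCa=4.5, mode="ktr_slack_restretch",
                            duration_s=3.0, release_time_s=1.5)
        fit = ktr_protocol(geom, par, variants["none"], "none", proto)
        assert fit.k_tr == pytest.approx(30.0, rel=0.02)

    def test_slack_only_mode_has_no_ktr(self, geom, params, variants):
        proto = SimProtocol(pCa=4.5, mode="slack_only", duration_s=3.0,
                            release_time_s=1.5)
        with pytest.raises(ValueError):
            ktr_protocol(geom, params, variants["none"], "none", proto)

    def test_phosphorylation_increases_force_at_physiological_calcium(
        self, geom, params, variants
    ):
        F_u = steady_state_force(geom, params, variants["none"], "none", 2.3, 5.8)
        F_p = steady_state_force(geom, params, variants["A"], "all", 2.3, 5.8)
        assert F_p > F_u

    def test_isometric_force_nonnegative(self, geom, params, variants):
        res = mean_field_simulate(geom, params, variants["none"], "none",
                                  SimProtocol(pCa=5.8, duration_s=2.0))
        assert np.all(res.force_pN >= 0)
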