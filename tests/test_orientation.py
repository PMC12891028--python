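import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thickfil.orientation import (
    EulerOrientation,
    MEMap,
    P2Transient,
    ProbeConstraint,
    degenerate_pair,
    euler_from_structure,
    euler_from_vectors,
    find_peaks,
    fit_p2_transient,
    max_entropy_map,
    p2_of_angle,
    p2_of_distribution,
    predicted_p2,
)


class TestOrderParameter:
    @pytest.mark.parametrize("theta,expected", [(0.0, 1.0), (90.0, -0.5),
                                                (54.7356103, 0.0), (180.0, 1.0)])
    def test_p2_reference_angles(self, theta, expected):
        assert p2_of_angle(theta) == pytest.approx(expected, abs=1e-6)

    def test_uniform_distribution_has_zero_p2(self):
        m = max_entropy_map([])
        assert p2_of_distribution(m) == pytest.approx(0.0, abs=1e-6)


class TestDegeneracy:
    def test_reference_pairs(self):
        d = degenerate_pair(EulerOrientation(60, 30))
        assert (d.beta, d.gamma) == (120.0, 210.0)
        d2 = degenerate_pair(EulerOrientation(90, 0))
        assert (d2.beta, d2.gamma) == (90.0, 180.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(beta=st.floats(0, 180), gamma=st.floats(0, 360, exclude_max=True))
    def test_involution(self, beta, gamma):
        o = EulerOrientation(beta, gamma)
        oo = degenerate_pair(degenerate_pair(o))
        assert oo.beta == pytest.approx(o.beta, abs=1e-9)
        assert oo.gamma % 360 == pytest.approx(o.gamma % 360, abs=1e-9)


def _helix(n=12, axis=np.array([0.0, 0.0, 1.0]), start=1):
    """Ideal alpha-helix CA trace along a given axis (1.5 A rise, 100 deg)."""
    axis = axis / np.linalg.norm(axis)
    # orthonormal frame
    tmp = np.array([1.0, 0.0, 0.0])
    if abs(tmp @ axis) > 0.9:
        tmp = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = np.arange(n)
    return (
        2.3 * (np.cos(np.deg2rad(100 * t))[:, None] * e1
               + np.sin(np.deg2rad(100 * t))[:, None] * e2)
        + 1.5 * t[:, None] * axis
    )


class TestEulerFromStructure:
    def test_parallel_helix_beta_zero(self):
        from thickfil.orientation import _lsq_axis

        coords = _helix(n=20)
        o = euler_from_vectors(
            _lsq_axis(coords), np.array([1.0, 0.0, 0.3]), [0, 0, 1]
        )
        assert o.beta == pytest.approx(0.0, abs=1.0)

    def test_perpendicular_helix_beta_ninety(self):
        o = euler_from_vectors([1, 0, 0], [0, 1, 0], [0, 0, 1])
        assert o.beta == pytest.approx(90.0)

    def test_gamma_zero_convention(self):
        # E-helix tilted in the x-z plane; reference vector in the same
        # plane on the axis side -> gamma = 0
        e = np.array([np.sin(0.6), 0.0, np.cos(0.6)])
        ref = np.array([0.0, 0.0, 1.0])
        o = euler_from_vectors(e, ref, [0, 0, 1])
        assert o.gamma == pytest.approx(0.0, abs=1e-6)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(3)
        e = rng.standard_normal(3)
        ref = rng.standard_normal(3)
        f = rng.standard_normal(3)
        o1 = euler_from_vectors(e, ref, f)
        # random rotation applied to everything
        q = np.linalg.qr(rng.standard_normal((3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        o2 = euler_from_vectors(q @ e, q @ ref, q @ f)
        assert o2.beta == pytest.approx(o1.beta, abs=1e-6)
        assert o2.gamma == pytest.approx(o1.gamma, abs=1e-6)

    def test_structure_file_roundtrip(self, tmp_path):
        """Synthetic helix PDB written via biotite recovers beta ~ tilt."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        tilt = np.deg2rad(35.0)
        axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        e_coords = _helix(19, axis=axis)  # ~5 full turns, clean axis
        ref_coords = _helix(8, axis=np.array([0.0, 1.0, 0.0])) + np.array([12.0, 0, 0])
        coords = np.vstack([e_coords, ref_coords])
        atoms = struc.AtomArray(coords.shape[0])
        atoms.coord = coords
        atoms.atom_name = np.array(["CA"] * len(coords))
        atoms.res_name = np.array(["ALA"] * len(coords))
        atoms.res_id = np.arange(1, len(coords) + 1)
        atoms.chain_id = np.array(["A"] * len(coords))
        atoms.element = np.array(["C"] * len(coords))
        path = tmp_path / "synthetic_helix.pdb"
        f = pdb.PDBFile()
        pdb.set_structure(f, atoms)
        f.write(str(path))

        o = euler_from_structure(str(path), (1, 19), (20, 27), [0, 0, 1])
        assert o.beta == pytest.approx(35.0, abs=2.0)

    def test_missing_residues_listed(self, tmp_path):
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        coords = _helix(3)
        atoms = struc.AtomArray(3)
        atoms.coord = coords
        atoms.atom_name = np.array(["CA"] * 3)
        atoms.res_name = np.array(["ALA"] * 3)
        atoms.res_id = np.arange(1, 4)
        atoms.chain_id = np.array(["A"] * 3)
        atoms.element = np.array(["C"] * 3)
        path = tmp_path / "short.pdb"
        f = pdb.PDBFile()
        pdb.set_structure(f, atoms)
        f.write(str(path))
        with pytest.raises(ValueError, match="missing"):
            euler_from_structure(str(path), (1, 8), (1, 3), [0, 0, 1])


class TestMaxEntropy:
    def test_no_constraints_uniform(self):
        m = max_entropy_map([])
        assert np.allclose(m.density, m.density.flat[0])
        assert find_peaks(m) == []

    def test_roundtrip_order_parameters(self):
        cons = [
            ProbeConstraint(axis=(0, 0, 1), p2=0.3, p4=0.05),
            ProbeConstraint(axis=(np.sin(1.0), 0, np.cos(1.0)), p2=-0.1, p4=0.02),
        ]
        m = max_entropy_map(cons)
        assert np.allclose(m.achieved[:, 0], [0.3, -0.1], atol=1e-4)
        assert np.allclose(m.achieved[:, 1], [0.05, 0.02], atol=1e-4)

    def test_density_normalized_and_degeneracy_symmetric(self):
        m = max_entropy_map([ProbeConstraint(axis=(0, 0, 1), p2=0.5, p4=0.2)])
        assert float((m.density * m.weights).sum()) == pytest.approx(1.0, abs=1e-4)
        d = m.density
        partner = np.flip(np.roll(d, d.shape[1] // 2, axis=1), axis=0)
        assert np.allclose(d, partner, atol=1e-10)

    def test_aligned_probe_concentrates_at_poles(self):
        m = max_entropy_map([ProbeConstraint(axis=(0, 0, 1), p2=0.95, p4=0.85)])
        # density at beta ~ 0/180 dominates the equator
        eq = m.density[m.density.shape[0] // 2].max()
        pole = m.density[0].max()
        assert pole > 10 * eq

    def test_infeasible_constraint_rejected(self):
        with pytest.raises(ValueError):
            ProbeConstraint(axis=(0, 0, 1), p2=1.4)

    def test_two_population_map_yields_two_peak_groups(self):
        """A density built from two blobs + degeneracy partners gives
        exactly two peak groups, each with its partner found."""
        beta = (np.arange(90) + 0.5) * 2.0
        gamma = np.arange(180) * 2.0
        B, G = np.meshgrid(beta, gamma, indexing="ij")

        def blob(b0, g0, width=12.0):
            dg = np.minimum(np.abs(G - g0), 360 - np.abs(G - g0))
            return np.exp(-((B - b0) ** 2 + dg**2) / (2 * width**2))

        dens = blob(60, 40) + blob(110, 300)
        dens += np.flip(np.roll(dens, 90, axis=1), axis=0)  # partners
        m = MEMap(beta, gamma, dens, np.zeros((0, 2)), np.zeros((0, 2)), ())
        groups = find_peaks(m, min_separation_deg=25, min_height_frac=0.4)
        assert len(groups) == 2
        assert all(g["partner"] is not None for g in groups)


class TestTransients:
    @staticmethod
    def _trace(ph1=40.0, ph2=13.0, act=-0.05, relaxed=0.1, frac=0.6,
               t_rel=1.0, slack=0.06, t_end=2.0, dt=1e-3, restretch=True):
        t = np.arange(0, t_end + dt / 2, dt)
        y = np.full_like(t, act)
        target = act + frac * (relaxed - act)
        m1 = t >= t_rel
        y[m1] = target - (target - act) * np.exp(-ph1 * (t[m1] - t_rel))
        events = {"release": t_rel}
        if restretch:
            t_rst = t_rel + slack
            y_rst = float(np.interp(t_rst, t, y))
            m2 = t >= t_rst
            y[m2] = act - (act - y_rst) * np.exp(-ph2 * (t[m2] - t_rst))
            events["restretch"] = t_rst
        return t, y, events

    def test_noiseless_exact_rate_recovery(self):
        t, y, events = self._trace()
        tr = fit_p2_transient(t, y, events)
        assert tr.ph1.rate == pytest.approx(40.0, rel=1e-3)
        assert tr.ph2.rate == pytest.approx(13.0, rel=1e-3)
        assert tr.p2_act == pytest.approx(-0.05, abs=1e-6)

    def test_noisy_rate_recovery_at_snr_20(self, rng):
        t, y, events = self._trace(slack=0.12, dt=5e-4)
        amp = 0.6 * 0.15
        tr = fit_p2_transient(t, y + rng.normal(0, amp / 20, y.size), events)
        assert tr.ph1.rate == pytest.approx(40.0, rel=0.05)
        assert tr.ph2.rate == pytest.approx(13.0, rel=0.05)

    def test_slack_only_has_no_phase2(self):
        t, y, events = self._trace(restretch=False)
        tr = fit_p2_transient(t, y, events)
        assert tr.ph2.absent
        assert tr.ph1.rate == pytest.approx(40.0, rel=1e-3)

    def test_flat_phase_flagged_absent(self):
        t = np.arange(0, 2, 1e-3)
        y = np.zeros_like(t)
        tr = fit_p2_transient(t, y, {"release": 1.0})
        assert tr.ph1.absent

    def test_p2_bounds_validated(self):
        with pytest.raises(ValueError):
            P2Transient(np.arange(3.0), np.array([0.0, 1.5, 0.0]))


class TestPredictedP2:
    def test_constant_occupancy_gives_constant_p2(self, geom, params, variants):
        from thickfil.sarcomere import SimResult

        T = 5
        occ = {("C", "blocked", False): np.tile([1.0, 0.0, 0.0], (T, 1))}
        res = SimResult(np.arange(T, dtype=float), np.zeros(T), occ,
                        {("C", "blocked", False): 10.0}, np.zeros(T))
        tr = predicted_p2(res, {"OFF": 0.2, "ON": 0.0, "FG": -0.3})
        assert np.allclose(tr.p2, 0.2)

    def test_activation_decreases_p2_when_fg_more_perpendicular(
        self, geom, params, variants
    ):
        from thickfil.sarcomere import SimProtocol, mean_field_simulate

        res = mean_field_simulate(geom, params, variants["none"], "none",
                                  SimProtocol(pCa=4.5, duration_s=2.0))
        basis = {"OFF": 0.15, "ON": 0.0, "FG": -0.25}
        tr = predicted_p2(res, basis)
        assert tr.p2[-1] < tr.p2[0]
        assert tr.p2.min() >= -0.25 - 1e-9 and tr.p2.max() <= 0.15 + 1e-9
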