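"""RLC-probe orientation analysis for polarized-fluorescence experiments.

A bifunctional rhodamine probe crosslinked along the RLC E-helix reports
the orientation of the myosin head's light-chain domain relative to the
filament axis.  The orientation of the RLC is described by two Euler
angles: beta, the angle between the E-helix and the filament axis, and
gamma, the rotation of the RLC about the E-helix vector.  Polarized
fluorescence determines the order parameters

    <P2> = <(3 cos^2 theta - 1)/2>,    <P4> (rank-4 Legendre average)

of each probe axis with respect to the filament axis, and cannot
distinguish (beta, gamma) from (180 - beta, gamma + 180): every
orientation population appears twice in the maps (the two sides of the
bipolar filament).

The maximum-entropy (ME) formalism recovers the broadest orientation
density rho(beta, gamma) consistent with the measured order parameters:

    rho ∝ exp( sum_j [ lambda_j2 P2(theta_j) + lambda_j4 P4(theta_j) ] )

with theta_j the polar angle of probe axis j after rotation by
(beta, gamma), and the Lagrange multipliers lambda solved so that the
achieved order parameters match the measurements.

The module also analyses time-resolved <P2> traces from slack-restretch
protocols: Phase 1 (after the release, heads detaching and partially
re-forming the OFF state) and Phase 2 (after the restretch, heads leaving
the OFF state and generating force) are each fitted by a single
exponential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize


# --------------------------------------------------------------------- #
# order parameters and Euler degeneracy
# --------------------------------------------------------------------- #
def p2_of_angle(theta_deg) -> np.ndarray | float:
    """Second-rank Legendre order parameter P2(theta) = (3 cos^2 - 1)/2."""
    c = np.cos(np.deg2rad(theta_deg))
    return (3.0 * c * c - 1.0) / 2.0


def p4_of_angle(theta_deg) -> np.ndarray | float:
    """Fourth-rank Legendre polynomial of cos(theta)."""
    c = np.cos(np.deg2rad(theta_deg))
    return (35.0 * c**4 - 30.0 * c**2 + 3.0) / 8.0


@dataclass(frozen=True)
class EulerOrientation:
    """(beta, gamma) in degrees; beta in [0, 180], gamma in [0, 360)."""

    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 180.0:
            raise ValueError("beta must be in [0, 180] degrees")
        object.__setattr__(self, "gamma", float(self.gamma) % 360.0)


def degenerate_pair(o: EulerOrientation) -> EulerOrientation:
    """The polarized-fluorescence-indistinguishable partner orientation."""
    return EulerOrientation(beta=180.0 - o.beta, gamma=(o.gamma + 180.0) % 360.0)


@dataclass(frozen=True)
class ProbeConstraint:
    """Measured order parameters of one probe axis fixed in the RLC frame.

    ``axis`` is the probe dipole direction in the RLC frame (unit vector;
    the E-helix is the local z-axis).  ``p2``/``p4`` are the measured
    <P2>/<P4> with respect to the filament axis.
    """

    axis: tuple
    p2: float
    p4: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.axis, float)
        n = np.linalg.norm(v)
        if n == 0:
            raise ValueError("probe axis must be nonzero")
        object.__setattr__(self, "axis", tuple(v / n))
        if not -0.5 - 1e-9 <= self.p2 <= 1.0 + 1e-9:
            raise ValueError("<P2> must lie in [-0.5, 1]")
        # rank-4 bound given p2 (necessary condition from the Legendre
        # expansion of a nonnegative density on [0, 1])
        if not -1.0 <= self.p4 <= 1.0:
            raise ValueError("<P4> must lie in [-1, 1]")


# --------------------------------------------------------------------- #
# Euler angles from atomic structures
# --------------------------------------------------------------------- #
def _lsq_axis(coords: np.ndarray) -> np.ndarray:
    """Least-squares direction of an atom chain (first principal axis),
    oriented from the first toward the last atom."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def euler_from_vectors(
    e_axis: np.ndarray, ref_vec: np.ndarray, filament_axis: np.ndarray
) -> EulerOrientation:
    """Euler angles of an E-helix axis and an in-plane reference vector.

    beta is the angle between the E-helix axis and the filament axis.
    gamma is the azimuth of the reference vector about the E-helix,
    with gamma = 0 when the reference vector lies in the plane spanned by
    the E-helix axis and the filament axis (on the filament-axis side).
    """
    f = np.asarray(filament_axis, float)
    if np.linalg.norm(f) == 0:
        raise ValueError("filament axis must be nonzero")
    f = f / np.linalg.norm(f)
    e = np.asarray(e_axis, float)
    e = e / np.linalg.norm(e)
    beta = np.rad2deg(np.arccos(np.clip(e @ f, -1.0, 1.0)))

    # component of the reference vector perpendicular to the E-helix
    r = np.asarray(ref_vec, float)
    r_perp = r - (r @ e) * e
    if np.linalg.norm(r_perp) < 1e-12:
        raise ValueError("reference vector is parallel to the E-helix axis")
    r_perp /= np.linalg.norm(r_perp)
    # in-plane direction: projection of the filament axis perpendicular to e
    f_perp = f - (f @ e) * e
    if np.linalg.norm(f_perp) < 1e-12:
        # beta = 0/180: gamma undefined up to the azimuth convention; pick
        # the lab x-axis projection as reference direction
        f_perp = np.array([1.0, 0.0, 0.0]) - e[0] * e
    f_perp /= np.linalg.norm(f_perp)
    cosg = np.clip(r_perp @ f_perp, -1.0, 1.0)
    sing = np.cross(f_perp, r_perp) @ e
    gamma = np.rad2deg(np.arctan2(sing, cosg)) % 360.0
    return EulerOrientation(beta=float(beta), gamma=float(gamma))


def euler_from_structure(
    path: str,
    e_helix_residues: tuple,
    ref_residues: tuple,
    filament_axis: Sequence[float],
    chain: str | None = None,
) -> EulerOrientation:
    """Euler angles of the RLC E-helix read from a PDB/mmCIF model.

    ``e_helix_residues`` and ``ref_residues`` are inclusive (start, end)
    residue-number spans; each must resolve to >= 4 CA atoms.  The
    reference span (e.g. the G-helix) fixes the gamma zero convention via
    the inter-helix vector from the E-helix centroid to the reference
    centroid.
    """
    import biotite.structure as struc
    import biotite.structure.io as strucio

    model = strucio.load_structure(path, model=1)
    ca = model[(model.atom_name == "CA")]
    if chain is not None:
        ca = ca[ca.chain_id == chain]

    def span_coords(span: tuple) -> np.ndarray:
        lo, hi = int(span[0]), int(span[1])
        sel = (ca.res_id >= lo) & (ca.res_id <= hi)
        coords = ca.coord[sel]
        if coords.shape[0] < 4:
            present = sorted(set(ca.res_id[sel].tolist()))
            missing = [r for r in range(lo, hi + 1) if r not in present]
            raise ValueError(
                f"residue span {span} resolves to {coords.shape[0]} CA atoms "
                f"(need >= 4); missing residues: {missing}"
            )
        order = np.argsort(ca.res_id[sel], kind="stable")
        return coords[order]

    e_coords = span_coords(e_helix_residues)
    r_coords = span_coords(ref_residues)
    e_axis = _lsq_axis(e_coords)
    ref_vec = r_coords.mean(axis=0) - e_coords.mean(axis=0)
    return euler_from_vectors(e_axis, ref_vec, np.asarray(filament_axis, float))


# --------------------------------------------------------------------- #
# maximum-entropy orientation maps
# --------------------------------------------------------------------- #
#: internal quadrature: Gauss-Legendre in cos(beta) x uniform periodic gamma,
#: spectrally accurate for the smooth exponential-family densities used here
_N_QUAD_BETA = 64
_N_QUAD_GAMMA = 180


def _quad_grid() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta_rad nodes, gamma_rad nodes, weight matrix) for sphere integrals."""
    u, wu = np.polynomial.legendre.leggauss(_N_QUAD_BETA)
    beta = np.arccos(u[::-1])
    wb = wu[::-1]
    gamma = 2.0 * np.pi * np.arange(_N_QUAD_GAMMA) / _N_QUAD_GAMMA
    wg = 2.0 * np.pi / _N_QUAD_GAMMA
    return beta, gamma, wb[:, None] * wg


@dataclass
class MEMap:
    beta_deg: np.ndarray  # (nb,) display-grid centers
    gamma_deg: np.ndarray  # (ng,)
    density: np.ndarray  # (nb, ng), integrates to 1 with sin(beta) measure
    lambdas: np.ndarray  # (n_probes, 2) Lagrange multipliers (P2, P4)
    achieved: np.ndarray  # (n_probes, 2) achieved order parameters
    constraints: tuple = ()

    @property
    def weights(self) -> np.ndarray:
        """Cell solid-angle weights for the display grid."""
        h = np.deg2rad(self.beta_deg[1] - self.beta_deg[0])
        edges_lo = np.deg2rad(self.beta_deg) - h / 2
        edges_hi = np.deg2rad(self.beta_deg) + h / 2
        dg = np.deg2rad(self.gamma_deg[1] - self.gamma_deg[0])
        wb = np.cos(edges_lo) - np.cos(edges_hi)
        return wb[:, None] * dg * np.ones((1, self.gamma_deg.size))

    def _log_density(self, beta_rad: np.ndarray, gamma_rad: np.ndarray) -> np.ndarray:
        logd = np.zeros((beta_rad.size, gamma_rad.size))
        for lam, c in zip(self.lambdas, self.constraints):
            ct = _probe_cos_theta(beta_rad, gamma_rad, np.asarray(c.axis))
            logd += lam[0] * (3.0 * ct**2 - 1.0) / 2.0
            logd += lam[1] * (35.0 * ct**4 - 30.0 * ct**2 + 3.0) / 8.0
        return logd

    def order_parameter(self, func) -> float:
        """Density-weighted average of func(beta_rad, gamma_rad) -> grid array,
        computed on the internal high-accuracy quadrature grid."""
        beta, gamma, w = _quad_grid()
        logd = self._log_density(beta, gamma)
        d = np.exp(logd - logd.max())
        z = np.sum(d * w)
        return float(np.sum(d * w * func(beta, gamma)) / z)


def _probe_cos_theta(
    beta_rad: np.ndarray, gamma_rad: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """cos(angle between probe axis and filament z) over a (beta, gamma) grid.

    The RLC frame is carried to the filament frame by R_y(beta) R_z(gamma);
    the filament-axis component of the rotated probe axis u is
        cos(theta) = -sin(beta) (u_x cos(gamma) - u_y sin(gamma))
                     + cos(beta) u_z.
    Azimuth about the filament axis is irrelevant (cylindrical symmetry).
    """
    ux, uy, uz = axis
    sb, cb = np.sin(beta_rad)[:, None], np.cos(beta_rad)[:, None]
    cg, sg = np.cos(gamma_rad)[None, :], np.sin(gamma_rad)[None, :]
    return -sb * (ux * cg - uy * sg) + cb * uz


def max_entropy_map(
    constraints: Sequence[ProbeConstraint],
    grid_deg: float = 2.0,
    use_p4: bool = True,
    tol: float = 1e-4,
) -> MEMap:
    """Maximum-entropy (beta, gamma) density matching probe order parameters.

    With no constraints the uniform density is returned.  The Lagrange
    multipliers are solved with a least-squares Newton iteration until
    every achieved order parameter matches its measurement within
    ``tol``; non-convergence raises with the residuals.  The returned map
    is exactly symmetric under (beta, gamma) -> (180 - beta, gamma + 180)
    because P2 and P4 are even in cos(theta).
    """
    nb = int(round(180.0 / grid_deg))
    ng = int(round(360.0 / grid_deg))
    beta = (np.arange(nb) + 0.5) * grid_deg
    gamma = np.arange(ng) * grid_deg
    constraints = tuple(constraints)

    def display_density(memap: MEMap) -> np.ndarray:
        brad, grad = np.deg2rad(beta), np.deg2rad(gamma)
        logd = memap._log_density(brad, grad)
        d = np.exp(logd - logd.max())
        return d / np.sum(d * memap.weights)

    if not constraints:
        out = MEMap(beta, gamma, np.empty((nb, ng)), np.zeros((0, 2)),
                    np.zeros((0, 2)), ())
        out.density = display_density(out)
        return out

    # basis functions P2/P4(theta_j) on the quadrature grid
    bq, gq, wq = _quad_grid()
    basis, meas = [], []
    for c in constraints:
        ct = _probe_cos_theta(bq, gq, np.asarray(c.axis))
        basis.append((3.0 * ct**2 - 1.0) / 2.0)
        meas.append(c.p2)
        if use_p4:
            basis.append((35.0 * ct**4 - 30.0 * ct**2 + 3.0) / 8.0)
            meas.append(c.p4)
    basis = np.stack(basis)  # (m, nbq, ngq)
    meas = np.asarray(meas)
    m = meas.size

    def achieved(lam: np.ndarray) -> np.ndarray:
        logd = np.tensordot(lam, basis, axes=(0, 0))
        d = np.exp(logd - logd.max())
        w = d * wq
        return np.tensordot(basis, w, axes=([1, 2], [0, 1])) / np.sum(w)

    def resid(lam: np.ndarray) -> np.ndarray:
        return achieved(lam) - meas

    sol = optimize.least_squares(resid, np.zeros(m), xtol=1e-15, ftol=1e-15,
                                 gtol=1e-15, max_nfev=2000)
    r = resid(sol.x)
    if np.max(np.abs(r)) > tol:
        raise RuntimeError(
            f"maximum-entropy solver did not converge: residuals {r}; the "
            "constraints may be infeasible for a nonnegative density"
        )
    lam2 = sol.x.reshape(len(constraints), 2 if use_p4 else 1)
    ach2 = achieved(sol.x).reshape(len(constraints), 2 if use_p4 else 1)
    if not use_p4:
        lam2 = np.hstack([lam2, np.zeros((len(constraints), 1))])
        ach2 = np.hstack([ach2, np.full((len(constraints), 1), np.nan)])
    out = MEMap(beta, gamma, np.empty((nb, ng)), lam2, ach2, constraints)
    out.density = display_density(out)
    return out


def p2_of_distribution(me_map: MEMap, axis: Sequence[float] = (0.0, 0.0, 1.0)) -> float:
    """<P2> of a probe axis under a solved (or uniform) ME density."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)

    def p2_func(beta_rad: np.ndarray, gamma_rad: np.ndarray) -> np.ndarray:
        ct = _probe_cos_theta(beta_rad, gamma_rad, u)
        return (3.0 * ct**2 - 1.0) / 2.0

    return me_map.order_parameter(p2_func)


def find_peaks(
    me_map: MEMap,
    min_separation_deg: float = 20.0,
    min_height_frac: float = 0.5,
) -> list[dict]:
    """Local maxima of the ME density, grouped with degeneracy partners.

    Returns a list of peak groups sorted by height; each group holds the
    representative peak (beta <= 90 preferred), its partner, and height.
    A flat map yields no peaks.
    """
    d = me_map.density
    nb, ng = d.shape
    if d.max() - d.min() < 1e-12 * max(d.max(), 1.0):
        return []
    thresh = min_height_frac * d.max()
    # local maxima on the torus in gamma, clipped in beta
    peaks = []
    for i in range(nb):
        for j in range(ng):
            v = d[i, j]
            if v < thresh:
                continue
            nbrs = [d[i, (j - 1) % ng], d[i, (j + 1) % ng]]
            if i > 0:
                nbrs.append(d[i - 1, j])
            if i < nb - 1:
                nbrs.append(d[i + 1, j])
            if all(v >= n for n in nbrs):
                peaks.append((float(me_map.beta_deg[i]), float(me_map.gamma_deg[j]), float(v)))
    peaks.sort(key=lambda p: -p[2])

    def ang_dist(a: tuple, b: tuple) -> float:
        # gamma distance shrinks with sin(beta) so the poles act as single
        # points (gamma is degenerate where the E-helix lies on the axis)
        dbeta = a[0] - b[0]
        dgamma = min(abs(a[1] - b[1]), 360.0 - abs(a[1] - b[1]))
        scale = np.sin(np.deg2rad(0.5 * (a[0] + b[0])))
        return float(np.hypot(dbeta, dgamma * scale))

    merged: list[tuple] = []
    for p in peaks:
        if all(ang_dist(p, q) > min_separation_deg for q in merged):
            merged.append(p)

    groups: list[dict] = []
    used = [False] * len(merged)
    for i, p in enumerate(merged):
        if used[i]:
            continue
        partner_o = degenerate_pair(EulerOrientation(p[0], p[1]))
        partner = None
        for j in range(i + 1, len(merged)):
            if used[j]:
                continue
            q = merged[j]
            if ang_dist((partner_o.beta, partner_o.gamma, 0.0), q) <= min_separation_deg:
                partner = q
                used[j] = True
                break
        used[i] = True
        rep, par = p, partner
        if par is not None and par[0] < rep[0] - 1e-9 and rep[0] > 90.0:
            rep, par = par, rep
        groups.append({
            "beta": rep[0], "gamma": rep[1], "height": rep[2],
            "partner": None if par is None else {"beta": par[0], "gamma": par[1]},
        })
    groups.sort(key=lambda g: -g["height"])
    return groups


# --------------------------------------------------------------------- #
# <P2> transients
# --------------------------------------------------------------------- #
@dataclass
class PhaseFit:
    rate: float  # s^-1
    amplitude: float  # signed delta <P2> of the phase
    start_value: float
    end_value: float
    absent: bool = False


@dataclass
class P2Transient:
    time_s: np.ndarray
    p2: np.ndarray
    events: Mapping[str, float] = field(default_factory=dict)
    ph1: PhaseFit | None = None
    ph2: PhaseFit | None = None
    p2_act: float | None = None  # steady <P2> during activation
    p2_relaxed: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, float)
        self.p2 = np.asarray(self.p2, float)
        if np.any(self.p2 < -0.5 - 1e-6) or np.any(self.p2 > 1.0 + 1e-6):
            raise ValueError("<P2> values must lie in [-0.5, 1]")


def _fit_single_exp(t: np.ndarray, y: np.ndarray, noise_floor: float) -> PhaseFit:
    y_inf0, y_00 = y[-1], y[0]
    amp0 = y_inf0 - y_00
    if abs(amp0) < max(noise_floor, 1e-12):
        return PhaseFit(rate=np.nan, amplitude=amp0, start_value=y_00,
                        end_value=y_inf0, absent=True)
    k0 = 3.0 / max(t[-1] - t[0], 1e-9)
    popt, _ = optimize.curve_fit(
        lambda t, yi, y0, k: yi - (yi - y0) * np.exp(-k * (t - t[0])),
        t, y, p0=[y_inf0, y_00, k0], maxfev=20000,
    )
    return PhaseFit(rate=abs(popt[2]), amplitude=popt[0] - popt[1],
                    start_value=popt[1], end_value=popt[0])


def fit_p2_transient(
    time_s: Sequence[float],
    p2: Sequence[float],
    events: Mapping[str, float],
    noise_floor: float = 0.002,
) -> P2Transient:
    """Two-phase analysis of a <P2> trace from a slack(-restretch) protocol.

    Phase 1 is fitted on [release, restretch) — the partial recovery of
    <P2> toward the relaxed value after the step release — and Phase 2 on
    [restretch, end] — the decline as heads leave the OFF state after the
    restretch.  Without a restretch event Phase 2 is reported absent.
    Phases with amplitude below ``noise_floor`` are flagged absent.
    """
    tr = P2Transient(np.asarray(time_s, float), np.asarray(p2, float), dict(events))
    t, y = tr.time_s, tr.p2
    if "release" not in events:
        raise ValueError("events must include 'release'")
    t_rel = events["release"]
    if not t[0] <= t_rel <= t[-1]:
        raise ValueError("release event outside the trace")
    t_rst = events.get("restretch")

    pre = t < t_rel
    if pre.sum() >= 2:
        tr.p2_act = float(np.mean(y[pre][-max(2, pre.sum() // 5):]))

    end1 = t_rst if t_rst is not None else t[-1]
    w1 = (t >= t_rel) & (t < end1)
    if w1.sum() < 10:
        raise ValueError("fewer than 10 points in the Phase 1 window")
    tr.ph1 = _fit_single_exp(t[w1], y[w1], noise_floor)
    tr.p2_relaxed = tr.ph1.end_value

    if t_rst is not None:
        w2 = t >= t_rst
        if w2.sum() < 10:
            raise ValueError("fewer than 10 points in the Phase 2 window")
        tr.ph2 = _fit_single_exp(t[w2], y[w2], noise_floor)
    else:
        tr.ph2 = PhaseFit(rate=np.nan, amplitude=0.0, start_value=np.nan,
                          end_value=np.nan, absent=True)
    return tr


def predicted_p2(sim_result, state_p2_basis: Mapping[str, float],
                 classes: Sequence[tuple] | None = None) -> P2Transient:
    """<P2>(t) predicted from simulator state occupancies.

    ``state_p2_basis`` maps state names (OFF, ON, FG) to basis <P2>
    values in [-0.5, 1]; the prediction is the occupancy-weighted mixture
    over the probe-exchanged head classes (all classes by default).
    """
    basis = np.array([state_p2_basis[s] for s in ("OFF", "ON", "FG")], float)
    if np.any(basis < -0.5) or np.any(basis > 1.0):
        raise ValueError("basis <P2> values must lie in [-0.5, 1]")
    occ = sim_result.mean_occupancy(classes)  # (T, 3)
    p2 = occ @ basis
    return P2Transient(sim_result.time_s, p2, dict(sim_result.events))
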