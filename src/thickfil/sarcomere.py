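"""Spatially explicit half-sarcomere model with thick-filament mechanosensing.

Myosin heads cycle independently through three functional states:

    OFF  --k1(F)-->  ON  --k3*act*ov-->  FG (force-generating)
    OFF <--k2------  ON <--k4----------  FG

The OFF->ON transition is *mechanosensitive*: its rate grows with the
total force borne by the thick filament,

    k1(F) = k1_0 * (1 + g * k_force * max(F, 0)),

where the gain factor g = phi_P (>= 1) for heads whose RLC is
phosphorylated *and* which are targeted by the active placement model,
and g = 1 otherwise.  Because phosphorylation multiplies the
force-dependent term only, it has no effect at zero load — consistent
with the observation that RLC phosphorylation barely changes relaxed
myosin orientation but accelerates force development after a restretch.

Three placement models map phosphorylation onto (zone, head role):

    A - blocked heads in the C-zone only;
    B - blocked heads in the whole filament (P, C and D zones);
    C - both blocked and free heads in the C-zone.

Thin-filament regulation: each of the 2 thin filaments per half-sarcomere
carries 26 regulatory units of 7 actins; unit activation by Ca2+ follows
kon = a_kon*[Ca]*(1 + a_coop * n_active_neighbors), koff = a_koff, and
an ON head can only enter FG where its crown overlaps an active unit.
A unit with an attached (FG) head cannot deactivate — tropomyosin cannot
re-block actin over a bound cross-bridge — which couples attachment back
into thin-filament activation and steepens the force-pCa relation.
The force sensed by the thick filament is the whole-filament active force
plus a linear titin-like passive force above slack length, which provides
the length dependence of activation.

Two engines are provided: a per-head Monte-Carlo simulation (tau-leaping)
and a deterministic mean-field ODE/steady-state engine used for fitting.
Desk-scale defaults: 1 thick + 2 thin filaments, dt = 0.5 ms, 4 s runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

from .geometry import FilamentGeometry, build_half_filament
from .imaging import OccupancyMap

STATES = ("OFF", "ON", "FG")
N_THIN_UNITS = 26
ACTINS_PER_UNIT = 7
N_THIN_FILAMENTS = 2


class SimulationError(RuntimeError):
    pass


# --------------------------------------------------------------------- #
# parameters and protocol
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class KineticParams:
    """Rate constants and mechanical constants of the head cycle.

    k1_0 : base OFF->ON rate, s^-1
    k_force : mechanosensing gain, pN^-1
    k2 : ON->OFF rate, s^-1
    k3 : attachment (ON->FG) rate at full activation/overlap, s^-1
    k4 : detachment (FG->ON) rate, s^-1
    f_head : force per attached head, pN
    a_kon : thin-filament unit activation rate, uM^-1 s^-1
    a_koff : unit deactivation rate, s^-1
    a_coop : nearest-neighbor cooperativity factor (dimensionless)
    phi_P : phosphorylation multiplier on k_force (>= 1)
    passive_gain : titin-like passive force per um of SL above slack, pN/um
    sl_slack_um : sarcomere slack length, um
    slack_detach_mult : detachment acceleration while mechanically unloaded
    """

    k1_0: float = 1.0
    k_force: float = 0.005
    k2: float = 100.0
    k3: float = 80.0
    k4: float = 12.0
    f_head: float = 8.0
    a_kon: float = 5.699
    a_koff: float = 100.0
    a_coop: float = 5.0
    phi_P: float = 3.0
    passive_gain: float = 210.0
    sl_slack_um: float = 1.8
    slack_detach_mult: float = 10.0

    def __post_init__(self) -> None:
        for name in ("k1_0", "k_force", "k2", "k3", "k4", "f_head", "a_kon",
                     "a_koff", "a_coop", "passive_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phi_P < 1.0:
            raise ValueError("phi_P must be >= 1")

    def passive_force(self, sl_um: float) -> float:
        return self.passive_gain * max(0.0, sl_um - self.sl_slack_um)


@dataclass(frozen=True)
class ModelVariant:
    """Which (zone, role) head classes respond to RLC phosphorylation."""

    name: str
    target_zones: frozenset = frozenset()
    target_roles: frozenset = frozenset()

    _CANON = {
        "A": ({"C"}, {"blocked"}),
        "B": ({"P", "C", "D"}, {"blocked"}),
        "C": ({"C"}, {"blocked", "free"}),
        "none": (set(), set()),
    }

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        if name not in cls._CANON:
            raise ValueError(f"unknown model variant {name!r}")
        zones, roles = cls._CANON[name]
        return cls(name=name, target_zones=frozenset(zones), target_roles=frozenset(roles))

    def targets(self, zone: str, role: str) -> bool:
        return zone in self.target_zones and role in self.target_roles


@dataclass(frozen=True)
class SimProtocol:
    sarcomere_length_um: float = 1.9
    pCa: float = 4.5
    duration_s: float = 4.0
    dt_s: float = 5e-4
    mode: str = "isometric"  # isometric | ktr_slack_restretch | slack_only
    release_time_s: float = 2.0
    slack_fraction: float = 0.1
    slack_duration_s: float = 0.02
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt must be > 0")
        if not 0.0 < self.slack_fraction <= 0.5:
            raise ValueError("slack_fraction must be in (0, 0.5]")
        if self.mode not in ("isometric", "ktr_slack_restretch", "slack_only"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")

    @property
    def ca_uM(self) -> float:
        return 10.0 ** (6.0 - self.pCa)


@dataclass
class SimResult:
    time_s: np.ndarray
    force_pN: np.ndarray
    #: occupancy traces per head class: {(zone, role, phosphorylated): (T, 3)}
    occupancy: dict
    class_counts: dict
    thin_active: np.ndarray
    events: dict = field(default_factory=dict)

    @property
    def force_norm(self) -> np.ndarray:
        peak = self.force_pN.max()
        return self.force_pN / peak if peak > 0 else self.force_pN

    def mean_occupancy(self, classes: Sequence[tuple] | None = None) -> np.ndarray:
        """Head-count-weighted mean state occupancy (T, 3) over classes."""
        keys = list(self.occupancy) if classes is None else list(classes)
        w = np.array([self.class_counts[k] for k in keys], dtype=float)
        stack = np.stack([self.occupancy[k] for k in keys])  # (C, T, 3)
        return np.tensordot(w / w.sum(), stack, axes=(0, 0))


@dataclass(frozen=True)
class HillFit:
    F_max: float
    pCa50: float
    n_H: float

    def __call__(self, pCa: np.ndarray) -> np.ndarray:
        pCa = np.asarray(pCa, dtype=float)
        return self.F_max / (1.0 + 10.0 ** (self.n_H * (pCa - self.pCa50)))


@dataclass(frozen=True)
class KtrFit:
    k_tr: float
    F_plateau: float
    F_start: float


# --------------------------------------------------------------------- #
# head classes
# --------------------------------------------------------------------- #
def resolve_phospho_map(
    geom: FilamentGeometry, phospho: OccupancyMap | str | None
) -> np.ndarray:
    """Per-crown phosphorylated fraction from an OccupancyMap or 'all'/'none'."""
    if phospho is None or phospho == "none":
        return np.zeros(geom.n_crowns_half)
    if phospho == "all":
        return np.ones(geom.n_crowns_half)
    if isinstance(phospho, OccupancyMap):
        occ = np.asarray(phospho.occupancy, dtype=float)
        if occ.size != geom.n_crowns_half:
            raise ValueError("occupancy length does not match geometry")
        return occ
    raise ValueError(f"cannot interpret phospho specification {phospho!r}")


@dataclass(frozen=True)
class HeadClasses:
    """Zone/role/phospho-aggregated head classes of one half filament."""

    keys: tuple  # tuple of (zone, role, phosphorylated)
    counts: np.ndarray  # heads per class
    targeted: np.ndarray  # bool: phosphorylation factor applies

    @classmethod
    def build(
        cls,
        geom: FilamentGeometry,
        variant: ModelVariant,
        phospho: OccupancyMap | str | None,
    ) -> "HeadClasses":
        occ = resolve_phospho_map(geom, phospho)
        zones = geom.zones
        per_role = geom.dimers_per_crown  # heads of one role per crown
        keys, counts, targeted = [], [], []
        for zone in ("P", "C", "D"):
            sel = zones == zone
            if not sel.any():
                continue
            for role in ("blocked", "free"):
                n_phos = per_role * float(occ[sel].sum())
                n_tot = per_role * float(sel.sum())
                for phos, n in ((True, n_phos), (False, n_tot - n_phos)):
                    if n <= 1e-12:
                        continue
                    keys.append((zone, role, phos))
                    counts.append(n)
                    targeted.append(phos and variant.targets(zone, role))
        return cls(tuple(keys), np.asarray(counts, float), np.asarray(targeted, bool))

    def overlap(self, geom: FilamentGeometry, sl_um: float) -> np.ndarray:
        """Mean actin-overlap fraction of each class's crowns at a given SL."""
        pos_um = geom.positions_nm / 1000.0
        reach = sl_um / 2.0 - geom.thin_filament_length_um
        crown_ov = (pos_um >= reach).astype(float)
        zones = geom.zones
        out = np.empty(len(self.keys))
        for i, (zone, _role, _p) in enumerate(self.keys):
            out[i] = crown_ov[zones == zone].mean()
        return out


def head_rates(
    state: str,
    zone: str,
    role: str,
    F_sense: float,
    thin_on: float,
    params: KineticParams,
    variant: ModelVariant,
    phosphorylated: bool,
    overlap: float = 1.0,
) -> dict:
    """Outgoing transition rates (s^-1) of one head in a given context."""
    if F_sense < 0:
        F_sense = 0.0
    g = params.phi_P if (phosphorylated and variant.targets(zone, role)) else 1.0
    if state == "OFF":
        return {"ON": params.k1_0 * (1.0 + g * params.k_force * F_sense)}
    if state == "ON":
        return {"OFF": params.k2, "FG": params.k3 * thin_on * overlap}
    if state == "FG":
        return {"ON": params.k4}
    raise ValueError(f"unknown state {state!r}")


# --------------------------------------------------------------------- #
# mean-field engine
# --------------------------------------------------------------------- #
def thin_activation_ss(
    ca_uM: float, params: KineticParams, koff_eff: float | None = None
) -> float:
    """Steady-state active-unit fraction (mean-field, 2 active neighbors max).

    Solves a_kon*Ca*(1 + 2*a_coop*a)*(1-a) = koff_eff*a for a in [0, 1].
    ``koff_eff`` defaults to a_koff; callers pass the cross-bridge-reduced
    deactivation rate a_koff*(1 - P(unit holds an attached head)).
    """
    b = params.a_kon * ca_uM
    c = params.a_coop
    koff = params.a_koff if koff_eff is None else koff_eff
    if b == 0:
        return 0.0
    if koff <= 0:
        return 1.0
    if c == 0:
        return b / (b + koff)
    # 2*b*c*a^2 + (koff - b*(2c - 1))*a - b = 0
    A, B, C = 2 * b * c, koff - b * (2 * c - 1.0), -b
    disc = B * B - 4 * A * C
    a = (-B + np.sqrt(disc)) / (2 * A)
    return float(np.clip(a, 0.0, 1.0))


def _unit_block_prob(fg_mean: float, heads_per_unit: float) -> float:
    """P(a regulatory unit holds >= 1 attached head), mean field."""
    return 1.0 - (1.0 - min(max(fg_mean, 0.0), 1.0)) ** heads_per_unit


def _class_fg(
    F_sense: float,
    k3a: np.ndarray,
    targeted: np.ndarray,
    params: KineticParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state (on, fg) occupancies per class at sensed force F."""
    g = np.where(targeted, params.phi_P, 1.0)
    k1 = params.k1_0 * (1.0 + g * params.k_force * max(F_sense, 0.0))
    on = k1 / (k1 * (1.0 + k3a / params.k4) + params.k2)
    fg = k3a * on / params.k4
    return on, fg


def steady_state_force(
    geom: FilamentGeometry,
    params: KineticParams,
    variant: ModelVariant,
    phospho: OccupancyMap | str | None,
    sl_um: float,
    pCa: float,
    classes: HeadClasses | None = None,
    return_occupancy: bool = False,
):
    """Self-consistent isometric steady-state active force (pN).

    The active force solves F = G(F + F_passive) where G maps sensed
    force to summed FG-head force through the per-class linear 3-state
    steady state.  A damped fixed-point iteration from F = 0 is used,
    matching the attractor an ODE run reaches from the relaxed state.
    """
    hc = classes if classes is not None else HeadClasses.build(geom, variant, phospho)
    ov = hc.overlap(geom, sl_um)
    ca = 10.0 ** (6.0 - pCa)
    F_pass = params.passive_force(sl_um)
    n_units = N_THIN_FILAMENTS * N_THIN_UNITS
    n_total = hc.counts.sum()
    heads_per_unit = float(hc.counts @ ov) / n_units

    def step(F: float, a: float) -> tuple[float, float, np.ndarray, np.ndarray]:
        k3a = params.k3 * a * ov
        on, fg = _class_fg(F + F_pass, k3a, hc.targeted, params)
        fg_mean = float(hc.counts @ (fg * ov)) / max(float(hc.counts @ ov), 1e-12)
        koff_eff = params.a_koff * (1.0 - _unit_block_prob(fg_mean, heads_per_unit))
        a_new = thin_activation_ss(ca, params, koff_eff)
        F_new = float(params.f_head * hc.counts @ fg)
        return F_new, a_new, on, fg

    F, a = 0.0, thin_activation_ss(ca, params)
    for _ in range(2000):
        F_new, a_new, on, fg = step(F, a)
        F_new = 0.5 * F + 0.5 * F_new
        a_new = 0.5 * a + 0.5 * a_new
        if abs(F_new - F) < 1e-10 * (1.0 + F_new) and abs(a_new - a) < 1e-12:
            F, a = F_new, a_new
            break
        F, a = F_new, a_new
    else:  # pragma: no cover - fallback for pathological gains
        warnings.warn("steady-state iteration hit the cap", RuntimeWarning)
    if not return_occupancy:
        return F
    _, _, on, fg = step(F, a)
    return F, on, fg, a


def mean_field_simulate(
    geom: FilamentGeometry,
    params: KineticParams,
    variant: ModelVariant,
    phospho: OccupancyMap | str | None,
    protocol: SimProtocol,
    y0: np.ndarray | None = None,
) -> SimResult:
    """Deterministic zone/role-aggregated ODE engine.

    State vector: [a, on_1, fg_1, ..., on_C, fg_C].  Slack phases are
    modeled as mechanically unloaded: sensed and reported force are zero,
    attachment is suspended (filaments slide) and detachment accelerated
    by ``slack_detach_mult``.
    """
    hc = HeadClasses.build(geom, variant, phospho)
    nC = len(hc.keys)
    sl0 = protocol.sarcomere_length_um
    sl_short = sl0 * (1.0 - protocol.slack_fraction)
    ca = protocol.ca_uM

    t_rel = protocol.release_time_s
    t_restretch = t_rel + protocol.slack_duration_s
    events: dict = {}
    if protocol.mode == "ktr_slack_restretch":
        events = {"release": t_rel, "restretch": t_restretch}
    elif protocol.mode == "slack_only":
        events = {"release": t_rel, "slack_takeup": t_restretch}

    def phase_at(t: float) -> str:
        if protocol.mode == "isometric" or t < t_rel:
            return "isometric"
        if protocol.mode == "ktr_slack_restretch":
            return "slack" if t < t_restretch else "isometric"
        # slack_only: unloaded slide until slack taken up, then redevelop
        return "slack" if t < t_restretch else "short_isometric"

    ov_iso = hc.overlap(geom, sl0)
    ov_short = hc.overlap(geom, sl_short)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        phase = phase_at(t)
        a = y[0]
        on = y[1 : 1 + nC]
        fg = y[1 + nC :]
        off = 1.0 - on - fg
        if phase == "slack":
            F_sense, k3a, k4 = 0.0, np.zeros(nC), params.k4 * params.slack_detach_mult
        else:
            sl = sl0 if phase == "isometric" else sl_short
            ov = ov_iso if phase == "isometric" else ov_short
            F_act = params.f_head * float(hc.counts @ fg)
            F_sense = F_act + params.passive_force(sl)
            k3a = params.k3 * a * ov
            k4 = params.k4
        g = np.where(hc.targeted, params.phi_P, 1.0)
        k1 = params.k1_0 * (1.0 + g * params.k_force * max(F_sense, 0.0))
        d_on = k1 * off - params.k2 * on - k3a * on + k4 * fg
        d_fg = k3a * on - k4 * fg
        ov_now = ov_iso if phase == "isometric" else ov_short
        denom = max(float(hc.counts @ ov_now), 1e-12)
        fg_mean = float(hc.counts @ (fg * ov_now)) / denom
        hpu = denom / (N_THIN_FILAMENTS * N_THIN_UNITS)
        koff_eff = params.a_koff * (1.0 - _unit_block_prob(fg_mean, hpu))
        d_a = params.a_kon * ca * (1.0 + 2.0 * params.a_coop * a) * (1.0 - a) \
            - koff_eff * a
        return np.concatenate([[d_a], d_on, d_fg])

    if y0 is None:
        y0 = np.zeros(1 + 2 * nC)  # relaxed start: all OFF, thin off
    t_eval = np.arange(0.0, protocol.duration_s + protocol.dt_s / 2, protocol.dt_s)
    breakpoints = sorted({t for t in (t_rel, t_restretch) if 0 < t < protocol.duration_s})
    sol_t, sol_y = [], []
    t0 = 0.0
    y = np.array(y0, dtype=float)
    for t1 in breakpoints + [protocol.duration_s]:
        seg = t_eval[(t_eval >= t0 - 1e-12) & (t_eval <= t1 + 1e-12)]
        sol = solve_ivp(rhs, (t0, t1), y, t_eval=seg, method="LSODA",
                        rtol=1e-7, atol=1e-9, max_step=protocol.dt_s * 20)
        if not sol.success:
            raise SimulationError(f"stiff integration failed: {sol.message}")
        sol_t.append(sol.t)
        sol_y.append(sol.y)
        y = sol.y[:, -1]
        t0 = t1
    t = np.concatenate(sol_t)
    Y = np.concatenate(sol_y, axis=1)
    # drop duplicated breakpoint samples
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    t, Y = t[keep], Y[:, keep]

    a_tr = Y[0]
    on_tr = Y[1 : 1 + nC]
    fg_tr = Y[1 + nC :]
    unloaded = np.array([phase_at(ti) == "slack" for ti in t])
    force = params.f_head * (hc.counts @ fg_tr)
    force = np.where(unloaded, 0.0, force)
    occupancy = {
        k: np.stack([1.0 - on_tr[i] - fg_tr[i], on_tr[i], fg_tr[i]], axis=1)
        for i, k in enumerate(hc.keys)
    }
    counts = {k: hc.counts[i] for i, k in enumerate(hc.keys)}
    return SimResult(t, force, occupancy, counts, a_tr, events)


# --------------------------------------------------------------------- #
# Monte-Carlo engine
# --------------------------------------------------------------------- #
def run_simulation(
    geom: FilamentGeometry,
    params: KineticParams,
    variant: ModelVariant,
    phospho: OccupancyMap | str | None,
    protocol: SimProtocol,
) -> SimResult:
    """Per-head stochastic simulation by tau-leaping at fixed dt.

    One thick filament (every head tracked individually) and
    ``N_THIN_FILAMENTS`` thin filaments of ``N_THIN_UNITS`` cooperative
    regulatory units.  Heads attach only where their crown overlaps an
    active unit on their paired thin filament.  Raises if any single-step
    probability rate*dt exceeds 0.1.
    """
    rng = np.random.default_rng(protocol.seed)
    dt = protocol.dt_s
    occ_map = resolve_phospho_map(geom, phospho)
    zones = geom.zones
    n_crowns = geom.n_crowns_half
    per_role = geom.dimers_per_crown

    # flat head arrays
    head_crown = np.repeat(np.arange(n_crowns), 2 * per_role)
    head_role = np.tile(
        np.array([0, 1] * per_role), n_crowns
    )  # 0 = blocked, 1 = free
    n_heads = head_crown.size
    # phosphorylation: per crown, a fraction occ of each role's heads
    head_phos = np.zeros(n_heads, dtype=bool)
    for c in range(n_crowns):
        for role in (0, 1):
            idx = np.flatnonzero((head_crown == c) & (head_role == role))
            k = int(round(occ_map[c] * idx.size))
            head_phos[idx[:k]] = True
    zone_arr = zones[head_crown]
    role_arr = np.where(head_role == 0, "blocked", "free")
    targeted = np.array(
        [variant.targets(z, r) for z, r in zip(zone_arr, role_arr)]
    ) & head_phos
    g_head = np.where(targeted, params.phi_P, 1.0)
    thin_of_head = head_crown % N_THIN_FILAMENTS

    sl0 = protocol.sarcomere_length_um
    sl_short = sl0 * (1.0 - protocol.slack_fraction)
    pos_um = geom.positions_nm / 1000.0
    L_thin = geom.thin_filament_length_um

    def crown_overlap(sl: float) -> np.ndarray:
        return pos_um >= (sl / 2.0 - L_thin)

    def unit_of_crown(sl: float) -> np.ndarray:
        """Map each crown to the thin regulatory unit covering its position."""
        z_pos = sl / 2.0 - pos_um  # distance from Z-disk, um
        u = np.floor(z_pos / (L_thin / N_THIN_UNITS)).astype(int)
        return np.clip(u, 0, N_THIN_UNITS - 1)

    ca = protocol.ca_uM
    t_rel = protocol.release_time_s
    t_restretch = t_rel + protocol.slack_duration_s
    events: dict = {}
    if protocol.mode == "ktr_slack_restretch":
        events = {"release": t_rel, "restretch": t_restretch}
    elif protocol.mode == "slack_only":
        events = {"release": t_rel, "slack_takeup": t_restretch}

    state = np.zeros(n_heads, dtype=np.int8)  # 0 OFF, 1 ON, 2 FG
    units = np.zeros((N_THIN_FILAMENTS, N_THIN_UNITS), dtype=bool)

    n_steps = int(round(protocol.duration_s / dt))
    t_out = np.arange(n_steps + 1) * dt
    force_out = np.zeros(n_steps + 1)
    thin_out = np.zeros(n_steps + 1)

    class_keys, class_masks = [], []
    for zone in ("P", "C", "D"):
        for role, rcode in (("blocked", 0), ("free", 1)):
            for phos in (True, False):
                m = (zone_arr == zone) & (head_role == rcode) & (head_phos == phos)
                if m.any():
                    class_keys.append((zone, role, phos))
                    class_masks.append(m)
    occ_out = {k: np.zeros((n_steps + 1, 3)) for k in class_keys}

    max_prob = 0.0

    def record(i: int, force: float) -> None:
        force_out[i] = force
        thin_out[i] = units.mean()
        for k, m in zip(class_keys, class_masks):
            s = state[m]
            occ_out[k][i] = [(s == 0).mean(), (s == 1).mean(), (s == 2).mean()]

    for i in range(n_steps + 1):
        t = t_out[i]
        if protocol.mode == "isometric" or t < t_rel:
            phase = "isometric"
        elif protocol.mode == "ktr_slack_restretch":
            phase = "slack" if t < t_restretch else "isometric"
        else:
            phase = "slack" if t < t_restretch else "short_isometric"
        sl = sl_short if phase == "short_isometric" else sl0
        ov = crown_overlap(sl)
        u_of_c = unit_of_crown(sl)

        F_act = params.f_head * float((state == 2).sum())
        if phase == "slack":
            F_sense, force_now, k4 = 0.0, 0.0, params.k4 * params.slack_detach_mult
            attach_ok = np.zeros(n_heads, dtype=bool)
        else:
            F_sense = F_act + params.passive_force(sl)
            force_now, k4 = F_act, params.k4
            attach_ok = ov[head_crown] & units[thin_of_head, u_of_c[head_crown]]

        record(i, force_now)
        if i == n_steps:
            break

        # thin filament units: cooperative activation
        nb = np.zeros_like(units, dtype=float)
        nb[:, 1:] += units[:, :-1]
        nb[:, :-1] += units[:, 1:]
        kon_u = params.a_kon * ca * (1.0 + params.a_coop * nb)
        # binary units flip with exact exponential probabilities, valid at
        # any rate*dt (neighbor counts frozen over one step); a unit holding
        # an attached head cannot deactivate
        held = np.zeros_like(units)
        fg_heads = np.flatnonzero(state == 2)
        if fg_heads.size:
            held[thin_of_head[fg_heads], u_of_c[head_crown[fg_heads]]] = True
        p_on = 1.0 - np.exp(-kon_u * dt)
        p_off = np.where(held, 0.0, 1.0 - np.exp(-params.a_koff * dt))
        r_u = rng.random(units.shape)
        units = np.where(units, r_u >= p_off, r_u < p_on)

        # head transitions: exact exponential exit probabilities over one
        # step, branched proportionally between competing destinations
        k1 = params.k1_0 * (1.0 + g_head * params.k_force * max(F_sense, 0.0))
        p = rng.random(n_heads)
        off_m = state == 0
        on_m = state == 1
        fg_m = state == 2
        k_on_out = params.k2 + params.k3 * attach_ok
        max_prob = max(
            max_prob, float(k1.max()) * dt, float(k_on_out.max()) * dt, k4 * dt
        )
        if max_prob > 0.1:
            raise SimulationError(
                f"dt too large: max single-step probability {max_prob:.3f} > 0.1"
            )
        p_off_on = 1.0 - np.exp(-k1 * dt)
        p_on_out = 1.0 - np.exp(-k_on_out * dt)
        p_on_off = p_on_out * params.k2 / k_on_out
        p_fg_on = 1.0 - np.exp(-k4 * dt)
        new_state = state.copy()
        new_state[off_m & (p < p_off_on)] = 1
        go_off = on_m & (p < p_on_off)
        go_fg = on_m & ~go_off & (p < p_on_out)
        new_state[go_off] = 0
        new_state[go_fg] = 2
        new_state[fg_m & (p < p_fg_on)] = 1
        state = new_state

    if not np.all(np.isfinite(force_out)):
        raise SimulationError("NaN force encountered")
    counts = {k: float(m.sum()) for k, m in zip(class_keys, class_masks)}
    return SimResult(t_out, force_out, occ_out, counts, thin_out, events)


# --------------------------------------------------------------------- #
# protocols and fits
# --------------------------------------------------------------------- #
def fit_hill(pCa: np.ndarray, force: np.ndarray) -> HillFit:
    """Fit F(pCa) = F_max / (1 + 10^{n_H (pCa - pCa50)})."""
    pCa = np.asarray(pCa, float)
    force = np.asarray(force, float)
    f50 = 0.5 * force.max()
    p0 = [force.max(), float(pCa[np.argmin(np.abs(force - f50))]), 3.0]
    popt, _ = optimize.curve_fit(
        lambda p, Fm, p50, nH: Fm / (1.0 + 10.0 ** (nH * (p - p50))),
        pCa,
        force,
        p0=p0,
        maxfev=20000,
    )
    fit = HillFit(F_max=popt[0], pCa50=popt[1], n_H=abs(popt[2]))
    if not (pCa.min() <= fit.pCa50 <= pCa.max()):
        warnings.warn("fitted pCa50 outside the sampled range: non-sigmoidal data",
                      RuntimeWarning)
    return fit


def force_pca_curve(
    geom: FilamentGeometry,
    params: KineticParams,
    variant: ModelVariant,
    phospho: OccupancyMap | str | None,
    sl_um: float,
    pCa_grid: Sequence[float],
    engine: str = "steady",
) -> tuple[HillFit, np.ndarray, np.ndarray]:
    """Steady-state force across a pCa grid plus a Hill fit.

    engine='steady' uses the self-consistent fixed point (fast,
    deterministic); 'mean_field' integrates the ODEs and averages the
    last 20 % of the trace; 'mc' does the same with the stochastic engine.
    """
    pCa_grid = np.asarray(pCa_grid, float)
    if pCa_grid.size < 6:
        raise ValueError("pCa grid must have at least 6 points")
    forces = np.empty(pCa_grid.size)
    if engine == "steady":
        hc = HeadClasses.build(geom, variant, phospho)
        for i, p in enumerate(pCa_grid):
            forces[i] = steady_state_force(
                geom, params, variant, phospho, sl_um, p, classes=hc
            )
    elif engine in ("mean_field", "mc"):
        run = mean_field_simulate if engine == "mean_field" else run_simulation
        for i, p in enumerate(pCa_grid):
            proto = SimProtocol(sarcomere_length_um=sl_um, pCa=float(p),
                                mode="isometric", seed=1234 + i)
            res = run(geom, params, variant, phospho, proto)
            tail = res.force_pN[int(0.8 * res.force_pN.size):]
            forces[i] = float(tail.mean())
    else:
        raise ValueError(f"unknown engine {engine!r}")
    fit = fit_hill(pCa_grid, forces)
    return fit, pCa_grid, forces


def ktr_protocol(
    geom: FilamentGeometry,
    params: KineticParams,
    variant: ModelVariant,
    phospho: OccupancyMap | str | None,
    protocol: SimProtocol,
    engine: str = "mean_field",
) -> KtrFit:
    """Rate of force redevelopment after a slack-restretch maneuver.

    Runs the protocol, then fits a single exponential
    F(t) = F_ss - (F_ss - F_0) exp(-k_tr (t - t_restretch)) to the force
    recovery after the restretch.
    """
    if protocol.mode != "ktr_slack_restretch":
        raise ValueError("ktr requires mode='ktr_slack_restretch' (restretch needed)")
    run = mean_field_simulate if engine == "mean_field" else run_simulation
    res = run(geom, params, variant, phospho, protocol)
    t_restretch = res.events["restretch"]
    pre = res.force_pN[res.time_s < res.events["release"]]
    plateau_before = float(pre[int(0.8 * pre.size):].mean())
    sel = res.time_s >= t_restretch
    t = res.time_s[sel] - t_restretch
    F = res.force_pN[sel]
    amplitude = F[-1] - F[0]
    if plateau_before <= 0 or amplitude < 0.05 * plateau_before:
        raise SimulationError("no force redevelopment after restretch")
    popt, _ = optimize.curve_fit(
        lambda t, Fss, F0, k: Fss - (Fss - F0) * np.exp(-k * t),
        t,
        F,
        p0=[F[-1], F[0], 10.0],
        maxfev=20000,
    )
    return KtrFit(k_tr=abs(popt[2]), F_plateau=popt[0], F_start=popt[1])


def default_setup(config: Mapping | None = None):
    """Convenience: (geometry, params) with the rodent defaults."""
    return build_half_filament(config), KineticParams()
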