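"""Seeded synthetic-data generators for every pipeline stage.

Each generator emits a dataset in the exact tabular schema the matching
analysis stage consumes, together with a ground-truth record of the
generating parameters, so the full pipeline can be exercised and its
parameter-recovery behavior quantified without any external data.

Named fixtures encode the study conditions:

``rat_myofibril_default``
    two-population RLC phosphorylation kinetics of rat ventricular
    myofibrils (EC50s 0.01/0.1 uM at 0.1 uM phosphatase; observed rates
    0.2/0.02 min^-1 at the default kinase dose);
``trabecula_shortSL`` / ``trabecula_longSL``
    normalized force-pCa Hill data at sarcomere length 1.9 / 2.3 um
    (pCa50 5.56 / 5.64 unphosphorylated, Hill coefficient 4);
``czone_5min`` / ``spillover_60pct``
    phospho-RLC axial profiles at ~0.2 (C-zone confined) and 0.6
    (D-zone spillover) mol Pi / mol RLC;
``slack_restretch_pre`` / ``slack_restretch_post``
    <P2> transients around a slack-restretch maneuver before / after
    phosphorylation (Ph2 ~13 -> ~24 s^-1, ktr ~13 -> ~16 s^-1; tissue
    magnitudes, encoded only as generator parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import imaging, kinetics
from .geometry import build_half_filament

KINDS = ("force_pca", "phospho_timecourse", "dose_response", "profile", "p2_transient")


@dataclass(frozen=True)
class GeneratorSpec:
    kind: str
    seed: int
    parameters: dict = field(default_factory=dict)
    noise: str = "gaussian"  # gaussian | poisson | none
    noise_scale: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; expected {KINDS}")
        if self.noise not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# --------------------------------------------------------------------- #
# named fixtures
# --------------------------------------------------------------------- #
FIXTURES: dict[str, GeneratorSpec] = {
    # myofibril kinetics: fast/slow kinase efficacies an order of magnitude
    # apart; dose-response EC50s 0.01 and 0.1 uM at 0.1 uM phosphatase
    "rat_myofibril_default": GeneratorSpec(
        kind="phospho_timecourse", seed=0, noise="gaussian", noise_scale=0.01,
        parameters={"kinase_uM": 0.02, "phosphatase_uM": 0.0, "p_max": 0.95,
                    "t_max_min": 180.0, "n_points": 40},
    ),
    "rat_dose_response": GeneratorSpec(
        kind="dose_response", seed=0, noise="gaussian", noise_scale=0.01,
        parameters={"phosphatase_uM": 0.1, "p_max": 0.95,
                    "K_min_uM": 1e-3, "K_max_uM": 10.0, "n_points": 12},
    ),
    # trabecula force-pCa operating points
    "trabecula_shortSL": GeneratorSpec(
        kind="force_pca", seed=0, noise="gaussian", noise_scale=0.03,
        parameters={"pCa50": 5.56, "n_H": 4.0, "n_points": 8,
                    "pCa_min": 4.8, "pCa_max": 6.4},
    ),
    "trabecula_longSL": GeneratorSpec(
        kind="force_pca", seed=0, noise="gaussian", noise_scale=0.03,
        parameters={"pCa50": 5.64, "n_H": 4.0, "n_points": 8,
                    "pCa_min": 4.8, "pCa_max": 6.4},
    ),
    # axial phospho-RLC profiles
    "czone_5min": GeneratorSpec(
        kind="profile", seed=0, noise="poisson", noise_scale=2000.0,
        parameters={"level": 0.2, "mode": "sequential"},
    ),
    "spillover_60pct": GeneratorSpec(
        kind="profile", seed=0, noise="poisson", noise_scale=2000.0,
        parameters={"level": 0.6, "mode": "sequential"},
    ),
    # <P2> slack-restretch transients (tissue-scale rates as parameters)
    "slack_restretch_pre": GeneratorSpec(
        kind="p2_transient", seed=0, noise="gaussian", noise_scale=0.002,
        parameters={"p2_act": -0.05, "p2_relaxed": 0.10, "ph1_rate": 40.0,
                    "ph1_recovery_frac": 0.6, "ph2_rate": 13.0, "ktr": 13.0},
    ),
    "slack_restretch_post": GeneratorSpec(
        kind="p2_transient", seed=0, noise="gaussian", noise_scale=0.002,
        parameters={"p2_act": -0.08, "p2_relaxed": 0.10, "ph1_rate": 40.0,
                    "ph1_recovery_frac": 0.6, "ph2_rate": 24.0, "ktr": 16.0},
    ),
}


def fixture_spec(name: str, seed: int | None = None) -> GeneratorSpec:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")
    spec = FIXTURES[name]
    if seed is not None:
        spec = GeneratorSpec(kind=spec.kind, seed=seed, parameters=spec.parameters,
                             noise=spec.noise, noise_scale=spec.noise_scale,
                             n_replicates=spec.n_replicates)
    return spec


# --------------------------------------------------------------------- #
# generators
# --------------------------------------------------------------------- #
def _gauss(rng: np.random.Generator, y: np.ndarray, scale: float) -> np.ndarray:
    return y + rng.normal(0.0, scale, size=y.shape)


def _gen_force_pca(spec: GeneratorSpec, rng) -> tuple[pd.DataFrame, dict]:
    p = {"pCa50": 5.56, "n_H": 4.0, "F_max": 1.0, "n_points": 8,
         "pCa_min": 4.8, "pCa_max": 6.4, **spec.parameters}
    grid = np.linspace(p["pCa_max"], p["pCa_min"], int(p["n_points"]))
    clean = p["F_max"] / (1.0 + 10.0 ** (p["n_H"] * (grid - p["pCa50"])))
    rows = []
    for rep in range(spec.n_replicates):
        y = clean.copy()
        if spec.noise == "gaussian":
            y = _gauss(rng, y, spec.noise_scale)
        rows.append(pd.DataFrame({"replicate": rep, "pCa": grid,
                                  "force_norm": np.clip(y, 0.0, None)}))
    return pd.concat(rows, ignore_index=True), p


def _default_popset(p: dict) -> kinetics.PopulationSet:
    return kinetics.default_population_set(
        kinase_conc=p.get("kinase_uM", 0.02),
        phosphatase_conc=p.get("phosphatase_uM", 0.0),
        p_max=p.get("p_max", 0.95),
    )


def _gen_timecourse(spec: GeneratorSpec, rng) -> tuple[pd.DataFrame, dict]:
    p = {"t_max_min": 180.0, "n_points": 40, **spec.parameters}
    popset = _default_popset(p)
    t = np.linspace(0.0, p["t_max_min"], int(p["n_points"]))
    _, total = kinetics.simulate_time_course(popset, t)
    rows = []
    for rep in range(spec.n_replicates):
        y = _gauss(rng, total, spec.noise_scale) if spec.noise == "gaussian" else total.copy()
        rows.append(pd.DataFrame({"replicate": rep, "t_min": t, "p_total": y}))
    truth = {**p, "rates_min^-1": kinetics.observed_rates(popset).tolist(),
             "fractions": [q.fraction for q in popset.populations]}
    return pd.concat(rows, ignore_index=True), truth


def _gen_dose_response(spec: GeneratorSpec, rng) -> tuple[pd.DataFrame, dict]:
    p = {"phosphatase_uM": 0.1, "K_min_uM": 1e-3, "K_max_uM": 10.0,
         "n_points": 12, **spec.parameters}
    popset = _default_popset(p)
    K = np.geomspace(p["K_min_uM"], p["K_max_uM"], int(p["n_points"]))
    clean = kinetics.steady_state_dose_response(popset, K)
    rows = []
    for rep in range(spec.n_replicates):
        y = clean.copy()
        if spec.noise == "gaussian":
            y = np.clip(_gauss(rng, y, spec.noise_scale), 0.0, None)
        rows.append(pd.DataFrame({"replicate": rep, "K_uM": K, "p_ss": y}))
    truth = {**p, "EC50s_uM": kinetics.population_ec50s(popset).tolist(),
             "fractions": [q.fraction for q in popset.populations]}
    return pd.concat(rows, ignore_index=True), truth


def _gen_profile(spec: GeneratorSpec, rng) -> tuple[pd.DataFrame, dict]:
    p = {"level": 0.2, "mode": "sequential",
         "psf_sigma_um": imaging.DEFAULT_PSF_SIGMA_UM,
         "pixel_um": imaging.DEFAULT_PIXEL_UM, **spec.parameters}
    geom = build_half_filament(p.get("geometry"))
    occ = imaging.occupancy_from_level(geom, p["level"], p["mode"])
    noise = "poisson" if spec.noise == "poisson" else "none"
    prof = imaging.render_profile(
        geom, occ, psf_sigma_um=p["psf_sigma_um"], pixel_um=p["pixel_um"],
        noise=noise, noise_scale=spec.noise_scale, seed=spec.seed,
    )
    df = pd.DataFrame({"position_um": prof.positions_um, "intensity": prof.intensities})
    return df, {**{k: v for k, v in p.items() if k != "geometry"},
                "occupancy": occ.occupancy.tolist()}


def _gen_p2_transient(spec: GeneratorSpec, rng) -> tuple[pd.DataFrame, dict]:
    p = {"p2_act": -0.05, "p2_relaxed": 0.10, "ph1_rate": 40.0,
         "ph1_recovery_frac": 0.6, "ph2_rate": 13.0, "ktr": 13.0,
         "t_release_s": 1.0, "slack_duration_s": 0.06, "t_end_s": 2.0,
         "dt_s": 1e-3, "omit_restretch": False, **spec.parameters}
    t = np.arange(0.0, p["t_end_s"] + p["dt_s"] / 2, p["dt_s"])
    t_rel = p["t_release_s"]
    t_rst = None if p["omit_restretch"] else t_rel + p["slack_duration_s"]
    y = np.full_like(t, p["p2_act"])
    # Phase 1: partial recovery toward the relaxed value after the release
    ph1_target = p["p2_act"] + p["ph1_recovery_frac"] * (p["p2_relaxed"] - p["p2_act"])
    m1 = t >= t_rel
    y[m1] = ph1_target - (ph1_target - p["p2_act"]) * np.exp(-p["ph1_rate"] * (t[m1] - t_rel))
    if t_rst is not None:
        y_rst = float(np.interp(t_rst, t, y))
        m2 = t >= t_rst
        # Phase 2: return to the activated level as heads leave the OFF state
        y[m2] = p["p2_act"] - (p["p2_act"] - y_rst) * np.exp(-p["ph2_rate"] * (t[m2] - t_rst))
    if spec.noise == "gaussian":
        y = _gauss(rng, y, spec.noise_scale)
    y = np.clip(y, -0.5, 1.0)
    df = pd.DataFrame({"t_s": t, "p2": y})
    events = {"release": t_rel}
    if t_rst is not None:
        events["restretch"] = t_rst
    return df, {**p, "events": events}


_GENERATORS = {
    "force_pca": _gen_force_pca,
    "phospho_timecourse": _gen_timecourse,
    "dose_response": _gen_dose_response,
    "profile": _gen_profile,
    "p2_transient": _gen_p2_transient,
}


def generate(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a dataset and its ground-truth record; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    df, truth = _GENERATORS[spec.kind](spec, rng)
    truth = {"kind": spec.kind, "seed": spec.seed, "noise": spec.noise,
             "noise_scale": spec.noise_scale, **truth}
    return df, truth


def write_dataset(spec: GeneratorSpec, outdir: str | Path, stem: str = "dataset"):
    """Write the CSV dataset plus a JSON ground-truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df, truth = generate(spec)
    csv_path = outdir / f"{stem}.csv"
    df.to_csv(csv_path, index=False)
    with open(outdir / f"{stem}.truth.json", "w") as fh:
        json.dump({"spec": asdict(spec), "truth": truth}, fh, indent=2, default=float)
    return csv_path
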