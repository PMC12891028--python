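"""End-to-end recipes chaining the analysis stages on synthetic fixtures.

Each recipe reproduces one figure-level workflow on generated data:

``kinetics``    time course + biexponential fit; dose-response + biphasic fit
``profiles``    MHC and phospho-RLC profile rendering + FWHM
``models``      baseline calibration, ensemble-MCMC fit of placement model A,
                pCa50 shifts, variant discrimination, ktr direction
``transients``  <P2> slack-restretch transients, two-phase fits, and the
                simulator-predicted <P2> trace

A recipe returns a report dict mapping each computed quantity to its value
and, where the underlying observable has a stated tolerance band, the band
and a pass flag.  Reports are deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import imaging, kinetics, orientation, synth
from .fitting import (
    model_pca50,
    reconstruct_experimental_targets,
    fit_model_to_targets,
    sum_squared_residuals,
)
from .geometry import build_half_filament
from .sarcomere import KineticParams, ModelVariant, SimProtocol, ktr_protocol

log = logging.getLogger("thickfil")

RECIPES = ("kinetics", "profiles", "models", "transients")
#: figure-oriented aliases
RECIPE_ALIASES = {
    "fig1_kinetics": "kinetics",
    "fig2_profiles": "profiles",
    "fig5_models": "models",
    "fig6_transients": "transients",
}


@dataclass
class RunConfig:
    outdir: str | Path | None = None
    seed: int = 0
    dry_run: bool = False
    #: reduced MCMC settings used by the models recipe
    n_walkers: int = 16
    n_steps: int = 150
    burn_in: int = 60
    extras: dict = field(default_factory=dict)


def _check(report: dict, name: str, value: float, lo: float | None = None,
           hi: float | None = None) -> None:
    entry: dict = {"value": float(value)}
    if lo is not None and hi is not None:
        entry["band"] = [lo, hi]
        entry["pass"] = bool(lo <= value <= hi)
    report[name] = entry


def recipe_kinetics(config: RunConfig) -> dict:
    """Two-population kinetics: biexponential time course + biphasic dose-response."""
    report: dict = {}
    popset = kinetics.default_population_set()
    t = np.linspace(0.0, 240.0, 60)
    _, total = kinetics.simulate_time_course(popset, t)
    fit = kinetics.fit_biexponential(t, total)
    _check(report, "biexp_k1_min^-1", fit.k1)
    _check(report, "biexp_k2_min^-1", fit.k2)
    _check(report, "biexp_rate_ratio", fit.k1 / fit.k2, 5.0, 20.0)

    dose = kinetics.default_population_set(phosphatase_conc=0.1)
    K = np.geomspace(1e-3, 10.0, 12)
    p = kinetics.steady_state_dose_response(dose, K)
    bi = kinetics.fit_biphasic(K, p)
    _check(report, "EC50_low_uM", bi.EC50_1, 0.008, 0.012)
    _check(report, "EC50_high_uM", bi.EC50_2, 0.08, 0.12)
    return report


def recipe_profiles(config: RunConfig) -> dict:
    """A-band profile FWHM for MHC, C-zone-confined, and spillover occupancy."""
    report: dict = {}
    geom = build_half_filament()
    mhc = imaging.render_profile(geom, None)
    _check(report, "fwhm_mhc_um", imaging.fwhm(mhc).fwhm_um, 1.4, 1.6)

    occ_pc = np.where(np.isin(geom.zones, ["P", "C"]), 1.0, 0.0)
    pc = imaging.OccupancyMap(occ_pc, float(occ_pc.mean()))
    _check(report, "fwhm_czone_um",
           imaging.fwhm(imaging.render_profile(geom, pc)).fwhm_um, 1.0, 1.2)

    spill = imaging.occupancy_from_level(geom, 0.6, "sequential")
    _check(report, "fwhm_spillover60_um",
           imaging.fwhm(imaging.render_profile(geom, spill)).fwhm_um, 1.15, 1.35)
    return report


def recipe_models(config: RunConfig) -> dict:
    """Calibrated + MCMC-fitted placement model A, with variant discrimination."""
    report: dict = {}
    geom = build_half_filament()
    vA = ModelVariant.from_name("A")
    vnone = ModelVariant.from_name("none")
    targets = reconstruct_experimental_targets()
    params, post = fit_model_to_targets(
        geom, vA, targets, n_walkers=config.n_walkers, n_steps=config.n_steps,
        burn_in=config.burn_in, seed=config.seed,
    )
    report["map_params"] = {k: float(v) for k, v in post.map_params.items()}
    report["acceptance_fraction"] = {"value": post.acceptance_fraction}

    shifts = {}
    for sl, label in ((1.9, "shortSL"), (2.3, "longSL")):
        base = model_pca50(geom, params, vnone, "none", sl).pCa50
        phos = model_pca50(geom, params, vA, "all", sl).pCa50
        shifts[label] = phos - base
    _check(report, "pca50_shift_shortSL", shifts["shortSL"], 0.05, 0.11)
    _check(report, "pca50_shift_longSL", shifts["longSL"], 0.08, 0.16)

    ssr = {v: sum_squared_residuals(geom, params, ModelVariant.from_name(v), targets)
           for v in ("A", "B", "C")}
    report["ssr"] = {k: float(v) for k, v in ssr.items()}
    _check(report, "ssr_ratio_B_over_A", ssr["B"] / ssr["A"], 2.0, np.inf)
    _check(report, "ssr_ratio_C_over_A", ssr["C"] / ssr["A"], 2.0, np.inf)

    proto = SimProtocol(sarcomere_length_um=2.3, pCa=4.5,
                        mode="ktr_slack_restretch", duration_s=5.0,
                        release_time_s=2.0)
    ktr_base = ktr_protocol(geom, params, vnone, "none", proto).k_tr
    ktr_phos = ktr_protocol(geom, params, vA, "all", proto).k_tr
    report["ktr_base_s^-1"] = {"value": float(ktr_base)}
    report["ktr_phos_s^-1"] = {"value": float(ktr_phos)}
    _check(report, "ktr_increase_s^-1", ktr_phos - ktr_base, 0.0, np.inf)
    return report


def recipe_transients(config: RunConfig) -> dict:
    """<P2> transient two-phase analysis on the pre/post fixtures."""
    report: dict = {}
    for name in ("slack_restretch_pre", "slack_restretch_post"):
        spec = synth.fixture_spec(name, seed=config.seed)
        df, truth = synth.generate(spec)
        tr = orientation.fit_p2_transient(df["t_s"], df["p2"], truth["events"])
        tag = name.rsplit("_", 1)[-1]
        report[f"ph1_rate_{tag}_s^-1"] = {"value": float(tr.ph1.rate),
                                          "truth": truth["ph1_rate"]}
        report[f"ph2_rate_{tag}_s^-1"] = {"value": float(tr.ph2.rate),
                                          "truth": truth["ph2_rate"]}
        report[f"ktr_{tag}_s^-1"] = {"value": truth["ktr"]}
    _check(report, "ph2_minus_ktr_post_s^-1",
           report["ph2_rate_post_s^-1"]["value"] - report["ktr_post_s^-1"]["value"],
           0.0, np.inf)
    return report


_RECIPE_FUNCS = {
    "kinetics": recipe_kinetics,
    "profiles": recipe_profiles,
    "models": recipe_models,
    "transients": recipe_transients,
}


def run_recipe(name: str, config: RunConfig | None = None) -> dict:
    """Run a named recipe; returns the report and optionally writes it.

    With ``config.dry_run`` the configuration is validated and an empty
    report returned without touching any outputs.
    """
    config = config or RunConfig()
    name = RECIPE_ALIASES.get(name, name)
    if name not in _RECIPE_FUNCS:
        raise KeyError(f"unknown recipe {name!r}; available: {RECIPES}")
    if config.dry_run:
        return {"recipe": name, "dry_run": True}
    log.info("running recipe %s (seed=%d)", name, config.seed)
    report = {"recipe": name, "seed": config.seed}
    report.update(_RECIPE_FUNCS[name](config))
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / f"{name}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        with open(outdir / f"{name}_report.txt", "w") as fh:
            for k, v in report.items():
                fh.write(f"{k}: {v}\n")
    return report


def report_passed(report: dict) -> bool:
    """True when every banded quantity in the report is inside its band."""
    return all(entry.get("pass", True) for entry in report.values()
               if isinstance(entry, dict))
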