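"""Two-population kinase/phosphatase model of cardiac RLC phosphorylation.

Cardiac myosin regulatory light chains (RLC) are phosphorylated at Ser15
by cardiac myosin light chain kinase (cMLCK) and dephosphorylated by
phosphatases such as PP1.  In intact myofibrils the steady-state
dose-response of RLC phosphorylation versus cMLCK concentration is
*biphasic* and the time course of phosphorylation is *biexponential*,
indicating (at least) two co-existing populations of myosin heads that are
phosphorylated with efficacies differing by about an order of magnitude —
plausibly heads in the cMyBP-C-containing C-zone versus the distal D-zone
of the thick filament.

Each population ``i`` follows mass-action kinase/phosphatase kinetics:

    dp_i/dt = k_P,i [K] (1 - p_i) - k_D,i [P] p_i

with closed-form solution

    p_i(t) = p_ss,i + (p0_i - p_ss,i) exp(-(k_P,i [K] + k_D,i [P]) t),
    p_ss,i = k_P,i [K] / (k_P,i [K] + k_D,i [P]).

The total phosphorylation level (mol Pi per mol RLC) is the
fraction-weighted sum scaled by a cap ``p_max`` on attainable
phosphorylation (e.g. ~0.95 under blebbistatin, ~0.65 under BDM).  The
steady-state level versus kinase concentration is a sum of hyperbolae with
EC50_i = (k_D,i / k_P,i) [P].

Default fixture (rat ventricular myofibrils): fast population = P+C-zone
heads (fraction 31/49), slow = D-zone heads (18/49); rate-constant ratios
chosen so that at [PP1] = 0.1 uM the two EC50s are 0.01 and 0.1 uM, and at
the default kinase dose the two observed rates are 0.2 and 0.02 min^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats


class FitError(RuntimeError):
    """Nonlinear least-squares fit failed to converge."""


# --------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------- #
@dataclass(frozen=True)
class PhosphoPopulation:
    """One kinetic class of RLC sites.

    fraction : share of total RLC in this class (0-1)
    k_P : kinase second-order rate constant, uM^-1 min^-1
    k_D : phosphatase second-order rate constant, uM^-1 min^-1
    p0 : initial phosphorylated fraction of this class
    """

    fraction: float
    k_P: float
    k_D: float
    p0: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        if self.k_P < 0 or self.k_D < 0:
            raise ValueError("rate constants must be >= 0")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")


@dataclass(frozen=True)
class PopulationSet:
    populations: tuple[PhosphoPopulation, ...]
    kinase_conc: float  # uM
    phosphatase_conc: float  # uM
    p_max: float = 1.0

    def __post_init__(self) -> None:
        total = sum(p.fraction for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {total}")
        if not 0.0 < self.p_max <= 1.0:
            raise ValueError("p_max must be in (0, 1]")
        if self.kinase_conc < 0 or self.phosphatase_conc < 0:
            raise ValueError("concentrations must be >= 0")

    def with_kinase(self, kinase_conc: float) -> "PopulationSet":
        return replace(self, kinase_conc=float(kinase_conc))


@dataclass(frozen=True)
class BiexpFit:
    """y(t) = offset + A1 (1 - e^{-k1 t}) + A2 (1 - e^{-k2 t}), k1 >= k2."""

    A1: float
    A2: float
    k1: float
    k2: float
    offset: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.A1 * (1 - np.exp(-self.k1 * t)) + self.A2 * (
            1 - np.exp(-self.k2 * t)
        )


@dataclass(frozen=True)
class MonoexpFit:
    A: float
    k_app: float
    offset: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + self.A * (1 - np.exp(-self.k_app * t))


@dataclass(frozen=True)
class BiphasicFit:
    """p(K) = baseline + A1 K/(K+EC50_1) + A2 K/(K+EC50_2), EC50_1 < EC50_2."""

    A1: float
    A2: float
    EC50_1: float
    EC50_2: float
    baseline: float = 0.0

    def __call__(self, K: np.ndarray) -> np.ndarray:
        K = np.asarray(K, dtype=float)
        return self.baseline + self.A1 * K / (K + self.EC50_1) + self.A2 * K / (
            K + self.EC50_2
        )


# --------------------------------------------------------------------- #
# default fixtures
# --------------------------------------------------------------------- #
def default_population_set(
    kinase_conc: float = 0.02,
    phosphatase_conc: float = 0.0,
    p_max: float = 0.95,
    fast_fraction: float = 31.0 / 49.0,
) -> PopulationSet:
    """Rat-myofibril two-population fixture.

    Fast population (P+C-zone heads by default; pass 27/49 for the
    C-only variant): k_P = 10, k_D = 1 uM^-1 min^-1 -> EC50 = 0.1 [P].
    Slow population (D-zone): k_P = 1, k_D = 1 -> EC50 = 1.0 [P].
    At [PP1] = 0.1 uM the EC50s are 0.01 and 0.1 uM; at the default
    kinase dose (0.02 uM, no phosphatase) the observed rates are 0.2 and
    0.02 min^-1, an order of magnitude apart.
    """
    fast = PhosphoPopulation(fraction=fast_fraction, k_P=10.0, k_D=1.0)
    slow = PhosphoPopulation(fraction=1.0 - fast_fraction, k_P=1.0, k_D=1.0)
    return PopulationSet(
        populations=(fast, slow),
        kinase_conc=kinase_conc,
        phosphatase_conc=phosphatase_conc,
        p_max=p_max,
    )


# --------------------------------------------------------------------- #
# forward models (closed form)
# --------------------------------------------------------------------- #
def observed_rates(popset: PopulationSet) -> np.ndarray:
    """Per-population observed relaxation rate k_P [K] + k_D [P], min^-1."""
    K, P = popset.kinase_conc, popset.phosphatase_conc
    return np.array([p.k_P * K + p.k_D * P for p in popset.populations])


def simulate_time_course(
    popset: PopulationSet, t_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Phosphorylation time course, closed form (no integrator error).

    Returns ``(per_population, total)`` where ``per_population`` has shape
    (n_populations, n_times) holding each class's phosphorylated fraction
    p_i(t), and ``total`` is p_max * sum_i f_i p_i(t) in mol Pi / mol RLC.

    If a population has zero total rate (no kinase and no phosphatase
    flux) its steady state is undefined; p(t) = p0 is returned and a
    warning is emitted if p0 differs from 0.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) < 0) or np.any(t < 0):
        raise ValueError("t_grid must be sorted and nonnegative")
    K, P = popset.kinase_conc, popset.phosphatase_conc
    per = np.empty((len(popset.populations), t.size))
    for i, pop in enumerate(popset.populations):
        rate = pop.k_P * K + pop.k_D * P
        if rate == 0.0:
            if pop.p0 != 0.0:
                warnings.warn(
                    "population with zero kinase/phosphatase flux: steady state "
                    "undefined; returning p(t) = p0",
                    RuntimeWarning,
                )
            per[i] = pop.p0
            continue
        p_ss = pop.k_P * K / rate
        per[i] = p_ss + (pop.p0 - p_ss) * np.exp(-rate * t)
    fractions = np.array([p.fraction for p in popset.populations])
    total = popset.p_max * fractions @ per
    return per, total


def steady_state_dose_response(
    popset: PopulationSet, K_grid: Sequence[float]
) -> np.ndarray:
    """Steady-state phosphorylation level versus kinase concentration.

    Each population contributes a hyperbola K/(K + EC50_i) with
    EC50_i = (k_D,i/k_P,i) [P]; the total is the fraction-weighted sum
    times p_max.  With [P] = 0 all EC50s collapse to zero (step function);
    this degenerate case is flagged with a warning.
    """
    K = np.asarray(K_grid, dtype=float)
    if np.any(K < 0):
        raise ValueError("kinase concentrations must be >= 0")
    P = popset.phosphatase_conc
    if P == 0.0:
        warnings.warn(
            "phosphatase concentration is 0: all EC50s are 0 (step response)",
            RuntimeWarning,
        )
    out = np.zeros_like(K)
    for pop in popset.populations:
        if pop.k_P == 0.0:
            continue
        ec50 = pop.k_D / pop.k_P * P
        with np.errstate(invalid="ignore", divide="ignore"):
            h = np.where(K + ec50 > 0, K / np.where(K + ec50 > 0, K + ec50, 1.0), 0.0)
        out += pop.fraction * h
    return popset.p_max * out


def population_ec50s(popset: PopulationSet) -> np.ndarray:
    """EC50 (uM kinase) per population at the set's phosphatase conc."""
    P = popset.phosphatase_conc
    return np.array(
        [p.k_D / p.k_P * P if p.k_P > 0 else np.inf for p in popset.populations]
    )


def biosensor_signal(
    p_total: np.ndarray,
    t_grid: Sequence[float],
    rlc_conc: float,
    gain: float = 1.0,
    background_rate: float = 0.0,
) -> np.ndarray:
    """Fluorescent ADP-biosensor readout of phosphate transfer.

    Each phosphotransfer produces one ADP, so the signal is strictly
    linear in phosphate incorporated:
    F(t) = gain * (rlc_conc * p_total(t) + background_rate * t),
    with ``background_rate`` (uM min^-1) covering basal ATP turnover.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    t = np.asarray(t_grid, dtype=float)
    return gain * (rlc_conc * np.asarray(p_total, dtype=float) + background_rate * t)


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #
def _rss(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.sum((y - yhat) ** 2))


def fit_monoexponential(t, y) -> MonoexpFit:
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    span = max(y.max() - y.min(), 1e-12)
    k0 = 1.0 / max(t.max() / 3.0, 1e-9)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, A, k, c: c + A * (1 - np.exp(-k * t)),
            t,
            y,
            p0=[span, k0, y[0]],
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FitError(f"monoexponential fit did not converge: {exc}") from exc
    return MonoexpFit(A=popt[0], k_app=abs(popt[1]), offset=popt[2])


def fit_biexponential(t, y, *, compare_monophasic: bool = False):
    """Least-squares biexponential fit, rates sorted descending (k1 >= k2).

    With ``compare_monophasic=True`` returns
    ``(BiexpFit, MonoexpFit, p_value)`` where the p-value is the extra
    sum-of-squares F-test for the two extra parameters; small p favours
    the biexponential model.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 6:
        raise ValueError("need at least 6 points for a biexponential fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")

    span = max(y.max() - y.min(), 1e-12)
    t_scale = max(t.max(), 1e-9)
    best = None
    # multistart over rate decades; biexponential fits are multimodal
    for fast in (10.0, 30.0, 100.0):
        for ratio in (5.0, 10.0, 50.0):
            p0 = [span / 2, span / 2, fast / t_scale, fast / ratio / t_scale, y[0]]
            try:
                popt, _ = optimize.curve_fit(
                    lambda t, A1, A2, k1, k2, c: c
                    + A1 * (1 - np.exp(-k1 * t))
                    + A2 * (1 - np.exp(-k2 * t)),
                    t,
                    y,
                    p0=p0,
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            fit = BiexpFit(
                A1=popt[0], A2=popt[1], k1=abs(popt[2]), k2=abs(popt[3]), offset=popt[4]
            )
            rss = _rss(y, fit(t))
            if best is None or rss < best[1]:
                best = (fit, rss)
    if best is None:
        raise FitError("biexponential fit did not converge from any start")
    fit, rss2 = best
    if fit.k1 < fit.k2:  # enforce k1 >= k2 convention
        fit = BiexpFit(A1=fit.A2, A2=fit.A1, k1=fit.k2, k2=fit.k1, offset=fit.offset)
    if fit.k2 > 0 and abs(fit.k1 - fit.k2) / fit.k2 < 0.05:
        warnings.warn("biexponential phases indistinguishable (k1 ~ k2)", RuntimeWarning)

    if not compare_monophasic:
        return fit
    mono = fit_monoexponential(t, y)
    rss1 = _rss(y, mono(t))
    df2 = t.size - 5
    scale = float(np.sum((y - y.mean()) ** 2))
    if rss1 <= 1e-10 * max(scale, 1e-300):
        # monophasic already fits to machine precision: the F-test is
        # degenerate and there is no support for a second phase
        p_value = 1.0
    elif df2 <= 0 or rss2 <= 0:
        p_value = 1.0
    else:
        f = max((rss1 - rss2) / 2.0, 0.0) / (rss2 / df2)
        p_value = float(stats.f.sf(f, 2, df2))
    return fit, mono, p_value


def fit_biphasic(K, p, weighting: str = "relative",
                 fit_baseline: bool = False) -> BiphasicFit:
    """Two-site hyperbolic fit of a steady-state dose-response.

    Requires >= 8 dose points spanning at least three decades.  EC50s are
    fitted on a log scale from a grid of start pairs and returned sorted
    ascending; a warning is emitted when they are within 10 % of each
    other (effectively monophasic data).

    ``weighting='relative'`` (default) minimizes relative residuals,
    appropriate for densitometric data whose noise scales with signal;
    ``weighting='none'`` uses plain least squares.  The baseline is fixed
    at zero by default (phosphorylation is zero without kinase); pass
    ``fit_baseline=True`` to free it.
    """
    K = np.asarray(K, float)
    p = np.asarray(p, float)
    if K.size < 8:
        raise ValueError("need at least 8 dose points")
    pos = K[K > 0]
    if pos.size == 0 or np.log10(pos.max() / pos.min()) < 3.0 - 1e-9:
        raise ValueError("dose points must span at least 3 decades")
    if weighting not in ("relative", "none"):
        raise ValueError("weighting must be 'relative' or 'none'")

    span = max(p.max() - p.min(), 1e-12)
    if weighting == "relative":
        w = np.maximum(np.abs(p), 0.05 * max(np.abs(p).max(), 1e-12))
    else:
        w = np.ones_like(p)

    def model(K, A1, A2, le1, le2, c=0.0):
        return c + A1 * K / (K + np.exp(le1)) + A2 * K / (K + np.exp(le2))

    best = None
    e_starts = np.geomspace(pos.min() * 3.0, pos.max() / 3.0, 5)
    for i, e1_0 in enumerate(e_starts):
        for e2_0 in e_starts[i + 1:]:
            p0 = [span / 2, span / 2, np.log(e1_0), np.log(e2_0)]
            if fit_baseline:
                p0.append(max(p.min(), 0.0))
            try:
                popt, _ = optimize.curve_fit(model, K, p, p0=p0, sigma=w,
                                             maxfev=20000)
            except RuntimeError:
                continue
            fit = BiphasicFit(
                A1=popt[0], A2=popt[1],
                EC50_1=float(np.exp(popt[2])), EC50_2=float(np.exp(popt[3])),
                baseline=float(popt[4]) if fit_baseline else 0.0,
            )
            rss = float(np.sum(((p - fit(K)) / w) ** 2))
            if best is None or rss < best[1]:
                best = (fit, rss)
    if best is None:
        raise FitError("biphasic fit did not converge from any start")
    fit = best[0]
    if fit.EC50_1 > fit.EC50_2:  # sort ascending, swap amplitudes with sites
        fit = BiphasicFit(
            A1=fit.A2, A2=fit.A1, EC50_1=fit.EC50_2, EC50_2=fit.EC50_1, baseline=fit.baseline
        )
    if fit.EC50_1 > 0 and (fit.EC50_2 - fit.EC50_1) / fit.EC50_1 < 0.10:
        warnings.warn("EC50s within 10%: dose-response effectively monophasic", RuntimeWarning)
    return fit
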