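"""Per-subject weighted nonlinear least-squares fitting of the delay model.

Both model variants are fit simultaneously to one subject's glucose,
insulin and glucagon series.  The free set is (a1, a2, gamma1, gamma2,
k1) plus the Hill coefficient(s); SG, n1, n2, V, K and the dose-response
prefactor are fixed at literature values; the delays tau, tau1, tau2 and
the glucagon recovery constant k2 are "manual" parameters held at
supplied values (or selected on a grid, :func:`grid_adjust_manual`).

Residuals are weighted by assay coefficients of variation (glucose 2%,
insulin 3%, glucagon 5.5%): ``r = (y_data - y_model) / (CV * y_data)``,
with an assay-floor on the denominator so points near the glucagon
detection limit do not get unbounded weight.  Minimization uses damped
Gauss-Newton (scipy ``least_squares``, trust-region-reflective) under
positivity bounds, with seeded multi-start because some fits are
sensitive to initial guesses.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.optimize import least_squares

from .infusion import InfusionSchedule, detect_hysteresis_anchor
from .model_core import (MGDL_PER_MM, HysteresisAnchor, InvalidArgumentError,
                         ModelParameters, SystemState, Variant)
from .series import ANALYTES, SubjectSeries
from .simulator import Trajectory, sample_at, simulate
from .stats_compare import aicc

#: Assay coefficients of variation (glucose, insulin, glucagon).
DEFAULT_CVS = (0.02, 0.03, 0.055)

#: Assay floors for the weight denominator, data units (mM, pM, pM).
DEFAULT_FLOORS = (0.5, 5.0, 1.0)

FREE_MODEL1 = ("a1", "a2", "gamma1", "gamma2", "k1", "h")
FREE_MODEL2 = ("a1", "a2", "gamma1", "gamma2", "k1", "h1", "h2")

#: Positivity bounds; Hill coefficients additionally confined to [0.5, 4].
DEFAULT_BOUNDS = {
    "a1": (1e-7, 1e-2),
    "a2": (1e-3, 5.0),
    "gamma1": (0.05, 100.0),
    "gamma2": (0.05, 100.0),
    "k1": (0.005, 2.0),
    "h": (0.5, 4.0),
    "h1": (0.5, 4.0),
    "h2": (0.5, 4.0),
}


class WeightingError(ValueError):
    """Nonpositive data value under CV weighting without a floor."""


class FitError(RuntimeError):
    """Fit could not be completed."""


@dataclass
class FitConfig:
    """Configuration of one subject-level fit."""

    variant: Variant = Variant.MODEL1_HILL
    weighting: str = "cv_weighted"           # or "unweighted"
    cvs: tuple = DEFAULT_CVS
    floors: tuple = DEFAULT_FLOORS
    manual: dict = field(default_factory=lambda: {
        "tau": 0.0, "tau1": 0.0, "tau2": 0.0, "k2": 0.5})
    group: str = "CS"                        # initial-guess range set
    initial_guess: Optional[dict] = None
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    n_starts: int = 5
    seed: int = 0
    integrator: str = "rk4"
    dt: float = 0.1
    fixed_overrides: dict = field(default_factory=dict)
    ftol: float = 1e-10
    xtol: float = 1e-10
    max_nfev: Optional[int] = None

    @property
    def free_names(self):
        return FREE_MODEL1 if Variant(self.variant) is Variant.MODEL1_HILL \
            else FREE_MODEL2


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics for one subject/model."""

    estimates: dict
    se: dict
    pvalues: dict
    fixed: dict
    manual: dict
    residuals: np.ndarray
    rss: float
    adj_r2: float
    aicc: float
    n: int
    p: int
    converged: bool
    weighting: str
    params: ModelParameters
    anchor: HysteresisAnchor
    schedule: InfusionSchedule
    initial_state: SystemState
    data_hash: str
    cost_history: np.ndarray
    message: str = ""
    se_available: bool = True

    @property
    def variant(self) -> Variant:
        return self.params.variant


def data_fingerprint(data: SubjectSeries) -> str:
    h = hashlib.sha1()
    for arr in (data.time_min, data.glucose_mM, data.insulin_pM,
                data.glucagon_pM):
        h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------

def weighted_residuals(data: SubjectSeries, sim: SubjectSeries,
                       cvs: Sequence[float] = DEFAULT_CVS,
                       mode: str = "cv_weighted",
                       floors: Sequence[float] = DEFAULT_FLOORS) -> np.ndarray:
    """Residual vector in fixed analyte order (glucose, insulin, glucagon),
    each block ordered by time.

    CV weighting divides by ``CV * max(y_data, floor)``; the floor bounds
    the influence of points near an assay's detection limit.  A
    nonpositive data value with a nonpositive floor is an error.
    """
    if not np.array_equal(data.time_min, sim.time_min):
        raise InvalidArgumentError("data and simulation sampling schedules differ")
    parts = []
    for name, cv, floor in zip(ANALYTES, cvs, floors):
        yd = data.analyte(name)
        ys = sim.analyte(name)
        if mode == "unweighted":
            parts.append(yd - ys)
            continue
        if mode != "cv_weighted":
            raise InvalidArgumentError(f"unknown weighting mode {mode!r}")
        denom = cv * np.maximum(yd, floor)
        if np.any(denom <= 0):
            raise WeightingError(
                f"nonpositive weight denominator for {name}")
        parts.append((yd - ys) / denom)
    return np.concatenate(parts)


def _weighted_data(data: SubjectSeries, cvs, mode, floors) -> np.ndarray:
    """Observations on the same (weighted) scale as the residuals."""
    parts = []
    for name, cv, floor in zip(ANALYTES, cvs, floors):
        yd = data.analyte(name)
        if mode == "unweighted":
            parts.append(yd)
        else:
            parts.append(yd / (cv * np.maximum(yd, floor)))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def regression_statistics(jac: np.ndarray, residuals: np.ndarray,
                          y_weighted: np.ndarray, n: int, p: int):
    """Asymptotic nonlinear-regression statistics.

    Returns ``(rss, se, pvalues, adj_r2, aicc_value, se_available)``.
    ``se`` are square roots of the diagonal of ``(J^T J)^{-1} s^2`` with
    ``s^2 = RSS/(n-p)``; p-values are two-sided Student-t with ``n-p``
    degrees of freedom; adjusted R^2 is computed on the fitted (weighted)
    scale; AICc uses the Gaussian RSS profile likelihood.
    """
    rss = float(residuals @ residuals)
    dof = n - p
    if dof < 1:
        raise InvalidArgumentError("statistics undefined for n <= p")
    s2 = rss / dof
    JtJ = jac.T @ jac
    se_available = True
    try:
        cov = np.linalg.inv(JtJ) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        if not np.all(np.isfinite(se)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se_available = False
        se = np.full(p, np.nan)
    tss = float(np.sum((y_weighted - y_weighted.mean()) ** 2))
    adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1)) if tss > 0 else np.nan
    aicc_value = aicc(rss, n, p) if rss > 0 else -np.inf
    return rss, se, adj_r2, aicc_value, se_available


def fit_statistics(result: FitResult):
    """(adjusted R^2, per-parameter SE, per-parameter p-value, AICc) of a
    converged fit."""
    if not result.converged:
        raise FitError("statistics requested for a non-converged fit")
    return result.adj_r2, result.se, result.pvalues, result.aicc


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess_vector(config: FitConfig):
    # midpoints of the cohort parameter ranges for the subject's group
    from .synthetic_data import GROUP_RANGES
    ranges = GROUP_RANGES[config.group]
    names = config.free_names
    guess = {}
    for name in names:
        if config.initial_guess and name in config.initial_guess:
            guess[name] = config.initial_guess[name]
        elif name in ("h1", "h2"):
            lo, hi = ranges.get(name, ranges["h"])
            guess[name] = 0.5 * (lo + hi)
        else:
            lo, hi = ranges[name]
            guess[name] = 0.5 * (lo + hi)
    return np.array([guess[n] for n in names])


def _build_params(x: np.ndarray, config: FitConfig) -> ModelParameters:
    names = config.free_names
    kw = dict(zip(names, (float(v) for v in x)))
    kw.update(config.manual)
    kw.update(config.fixed_overrides)
    kw["variant"] = Variant(config.variant)
    return ModelParameters(**kw)


def fit_model(data: SubjectSeries, schedule: InfusionSchedule,
              config: Optional[FitConfig] = None) -> FitResult:
    """Fit one model variant to one subject's three-analyte series.

    The hysteresis anchor is detected from the measured glucose profile;
    the initial state is the mean of the baseline (t <= 0) samples; the
    free parameters are estimated under positivity bounds with seeded
    multi-start, keeping the lowest weighted SSE.
    """
    config = config or FitConfig()
    anchor = detect_hysteresis_anchor(data)
    g0, i0, a0 = data.baseline_means()
    initial = SystemState(t=0.0, G=g0 * MGDL_PER_MM, I=i0 / 10.0, A=a0)
    t_end = float(max(data.time_min[-1], schedule.t_end))
    names = config.free_names
    lb = np.array([config.bounds[n][0] for n in names])
    ub = np.array([config.bounds[n][1] for n in names])
    cost_log = []

    def residual(x):
        params = _build_params(x, config)
        traj = simulate(params, schedule, anchor, initial, t_end=t_end,
                        method=config.integrator, dt=config.dt)
        sim = sample_at(traj, data.time_min)
        r = weighted_residuals(data, sim, config.cvs, config.weighting,
                               config.floors)
        cost_log.append(0.5 * float(r @ r))
        return r

    x0 = np.clip(_initial_guess_vector(config), lb, ub)
    rng = np.random.default_rng(config.seed)
    starts = [x0]
    for _ in range(max(0, config.n_starts - 1)):
        lo = np.maximum(lb, x0 / 5.0)
        hi = np.minimum(ub, x0 * 5.0)
        starts.append(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    best = None
    message = ""
    for start in starts:
        try:
            sol = least_squares(residual, start, bounds=(lb, ub),
                                method="trf", x_scale=np.abs(start),
                                ftol=config.ftol, xtol=config.xtol,
                                max_nfev=config.max_nfev)
        except Exception as exc:  # pragma: no cover - solver pathologies
            message = str(exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(f"all starts failed: {message}")

    n = data.n_observations
    p = len(names)
    y_w = _weighted_data(data, config.cvs, config.weighting, config.floors)
    rss, se, adj_r2, aicc_value, se_ok = regression_statistics(
        best.jac, best.fun, y_w, n, p)
    dof = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = best.x / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    params = _build_params(best.x, config)
    return FitResult(
        estimates=dict(zip(names, map(float, best.x))),
        se=dict(zip(names, map(float, se))),
        pvalues=dict(zip(names, map(float, pvals))),
        fixed={k: getattr(params, k) for k in
               ("SG", "n1", "n2", "K", "psi_scale", "V")},
        manual=dict(config.manual),
        residuals=best.fun,
        rss=rss,
        adj_r2=adj_r2,
        aicc=aicc_value,
        n=n,
        p=p,
        converged=bool(best.status > 0),
        weighting=config.weighting,
        params=params,
        anchor=anchor,
        schedule=schedule,
        initial_state=initial,
        data_hash=data_fingerprint(data),
        cost_history=np.asarray(cost_log),
        message=best.message,
        se_available=se_ok,
    )


def grid_adjust_manual(data: SubjectSeries, schedule: InfusionSchedule,
                       grids: dict, config: Optional[FitConfig] = None):
    """Select the manual parameters (tau, tau1, tau2, k2) on finite grids.

    Runs :func:`fit_model` at every grid tuple and returns
    ``(best_manual_dict, best_fit)`` by weighted SSE; candidates are
    visited in ascending (tau, tau1, tau2, k2) order and only strict
    improvements are accepted, so ties resolve toward smaller delays,
    then smaller k2.
    """
    config = config or FitConfig()
    names = ("tau", "tau1", "tau2", "k2")
    axes = []
    for name in names:
        vals = grids.get(name, [config.manual.get(name, 0.0)])
        if len(vals) == 0:
            raise InvalidArgumentError(f"empty grid for {name}")
        axes.append(sorted(vals))
    best_fit, best_manual = None, None
    for combo in itertools.product(*axes):
        manual = dict(zip(names, combo))
        fit = fit_model(data, schedule, replace(config, manual=manual))
        if best_fit is None or fit.rss < best_fit.rss:
            best_fit, best_manual = fit, manual
    return best_manual, best_fit
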