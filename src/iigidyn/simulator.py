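"""Method-of-steps integration of the three-state delay system.

Two integration backends are provided:

* ``"adaptive"`` — scipy ``solve_ivp`` (RK45) restarted at every
  discontinuity image (infusion-block edges shifted by the circulation
  delay, the hysteresis switch, and the ends of the constant history),
  with segment lengths capped at the smallest positive state delay so
  that delayed-glucose lookups always fall in completed segments.  This
  is the high-accuracy default for forward simulation and reporting.
* ``"rk4"`` — a numba-compiled fixed-step classical Runge-Kutta
  method-of-steps on the same restart grid, with cubic-Hermite
  interpolation of delayed glucose.  Used inside the fitting loop, where
  a smooth, deterministic objective and raw speed matter more than
  adaptive error control.

The history for ``t <= 0`` is the constant initial state: subjects enter
the experiment at an overnight-fast steady state.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicHermiteSpline

from .model_core import (
    MGDL_PER_MM, HysteresisAnchor, InvalidArgumentError, ModelParameters,
    SystemState, Variant, RISING_ONLY_ANCHOR, c1_adjustment, mgdl_to_mM,
    solve_equilibrium,
)
from .infusion import InfusionSchedule, build_infusion_rate, delayed_rate
from .series import DEFAULT_SCHEDULE, SubjectSeries

#: Negative overshoot beyond this (internal units) is an integration error;
#: values inside [-NEG_TOL, 0) are clamped to 0 at sampling only.
NEG_TOL = 1e-8


class IntegrationError(RuntimeError):
    """Solver failure or state escaping the physical region."""


# ---------------------------------------------------------------------------
# jitted fixed-step core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _hermite(s, ts, Gs, Ds, k, g_hist):
    """Cubic-Hermite lookup of a stored component at time ``s`` using the
    first ``k+1`` filled nodes; constant ``g_hist`` for ``s <= ts[0]``."""
    if s <= ts[0]:
        return g_hist
    i = np.searchsorted(ts[: k + 1], s) - 1
    if i >= k:
        return Gs[k]
    h = ts[i + 1] - ts[i]
    th = (s - ts[i]) / h
    th2 = th * th
    th3 = th2 * th
    return ((2 * th3 - 3 * th2 + 1) * Gs[i]
            + (th3 - 2 * th2 + th) * h * Ds[i]
            + (-2 * th3 + 3 * th2) * Gs[i + 1]
            + (th3 - th2) * h * Ds[i + 1])


@njit(cache=True)
def _rhs_jit(t, G, I, A, ts, Gs, Ds, k, G0,
             SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
             h_rise, h_fall, C1, t_hyst, yshift,
             tau, tau1, tau2, rates, block_min, rate_t_end):
    # delayed glucose, mM (internal storage is mg/dL)
    if tau1 > 0.0:
        gd1 = _hermite(t - tau1, ts, Gs, Ds, k, G0) / MGDL_PER_MM
    else:
        gd1 = G / MGDL_PER_MM
    if tau2 > 0.0:
        gd2 = _hermite(t - tau2, ts, Gs, Ds, k, G0) / MGDL_PER_MM
    else:
        gd2 = G / MGDL_PER_MM
    if gd1 < 0.0:
        gd1 = 0.0
    if gd2 < 0.0:
        gd2 = 0.0
    # insulin secretion drive
    if t < t_hyst:
        r = (gd1 / K) ** h_rise
        psi = psi_scale * r / (1.0 + r)
    else:
        r = (gd1 / K) ** h_fall
        psi = C1 * r / (1.0 + r)
    # glucagon secretion drive
    if t < t_hyst:
        phi = math.exp(-k1 * gd2)
    else:
        phi = math.exp(-k2 * gd2) + yshift
    # delayed infusion rate
    trt = t - tau
    if 0.0 <= trt < rate_t_end:
        idx = int(trt / block_min)
        if idx >= rates.size:
            idx = rates.size - 1
        R = rates[idx]
    else:
        R = 0.0
    dG = -(SG + a1 * I) * G + a2 * A + R / V
    dI = -n1 * I + g1 * psi
    dA = -n2 * A + g2 * phi
    return dG, dI, dA


@njit(cache=True)
def _integrate_rk4(ts, y0, SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K,
                   psi_scale, h_rise, h_fall, C1, t_hyst, yshift,
                   tau, tau1, tau2, rates, block_min, rate_t_end):
    n = ts.size
    Y = np.empty((3, n))
    D = np.empty((3, n))
    Y[:, 0] = y0
    G0 = y0[0]
    for k in range(n - 1):
        t = ts[k]
        h = ts[k + 1] - t
        G, I, A = Y[0, k], Y[1, k], Y[2, k]
        d1 = _rhs_jit(t, G, I, A, ts, Y[0], D[0], k, G0,
                      SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
                      h_rise, h_fall, C1, t_hyst, yshift,
                      tau, tau1, tau2, rates, block_min, rate_t_end)
        D[0, k], D[1, k], D[2, k] = d1
        d2 = _rhs_jit(t + 0.5 * h, G + 0.5 * h * d1[0], I + 0.5 * h * d1[1],
                      A + 0.5 * h * d1[2], ts, Y[0], D[0], k, G0,
                      SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
                      h_rise, h_fall, C1, t_hyst, yshift,
                      tau, tau1, tau2, rates, block_min, rate_t_end)
        d3 = _rhs_jit(t + 0.5 * h, G + 0.5 * h * d2[0], I + 0.5 * h * d2[1],
                      A + 0.5 * h * d2[2], ts, Y[0], D[0], k, G0,
                      SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
                      h_rise, h_fall, C1, t_hyst, yshift,
                      tau, tau1, tau2, rates, block_min, rate_t_end)
        d4 = _rhs_jit(t + h, G + h * d3[0], I + h * d3[1], A + h * d3[2],
                      ts, Y[0], D[0], k, G0,
                      SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
                      h_rise, h_fall, C1, t_hyst, yshift,
                      tau, tau1, tau2, rates, block_min, rate_t_end)
        Y[0, k + 1] = G + h / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        Y[1, k + 1] = I + h / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        Y[2, k + 1] = A + h / 6.0 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
    dn = _rhs_jit(ts[n - 1], Y[0, n - 1], Y[1, n - 1], Y[2, n - 1],
                  ts, Y[0], D[0], n - 1, G0,
                  SG, a1, a2, V, n1, n2, g1, g2, k1, k2, K, psi_scale,
                  h_rise, h_fall, C1, t_hyst, yshift,
                  tau, tau1, tau2, rates, block_min, rate_t_end)
    D[0, n - 1], D[1, n - 1], D[2, n - 1] = dn
    return Y, D


# ---------------------------------------------------------------------------
# trajectory container
# ---------------------------------------------------------------------------

class Trajectory:
    """Dense interpolable solution of the delay system.

    Covers ``[-max_delay, t_end]``; for ``t <= 0`` the constant history
    (the initial state) is returned.  Concentrations are internal units
    (G mg/dL, I 10 pM, A pM); conversion to data units happens in
    :func:`sample_at`.
    """

    def __init__(self, history, t_start, t_end, spline=None, segments=None,
                 meta=None):
        self.history = np.asarray(history, dtype=float)  # (G0, I0, A0)
        self.t_start = float(t_start)
        self.t_end = float(t_end)
        self._spline = spline            # CubicHermiteSpline over [0, t_end]
        self._segments = segments or []  # [(t0, t1, OdeSolution)]
        self.meta = meta or {}

    def eval_internal(self, t):
        """State (3, n) in internal units at times ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t > self.t_end + 1e-12):
            raise IntegrationError(
                f"query beyond trajectory end t={self.t_end}")
        out = np.empty((3, t.size))
        past = t <= 0
        out[:, past] = self.history[:, None]
        future = ~past
        if future.any():
            tf = np.clip(t[future], 0.0, self.t_end)
            if self._spline is not None:
                out[:, future] = self._spline(tf)
            else:
                vals = np.empty((3, tf.size))
                starts = [s[0] for s in self._segments]
                for j, tv in enumerate(tf):
                    i = bisect.bisect_right(starts, tv) - 1
                    i = max(0, min(i, len(self._segments) - 1))
                    vals[:, j] = self._segments[i][2](tv)
                out[:, future] = vals
        return out

    def glucose_mM(self, t):
        return self.eval_internal(t)[0] / MGDL_PER_MM


def sample_at(traj: Trajectory, times=None, subject_id=None) -> SubjectSeries:
    """Sample a trajectory at the experimental schedule, in data units.

    Values in ``[-1e-8, 0)`` (solver roundoff) are clamped to zero; more
    negative values raise :class:`IntegrationError`.
    """
    if times is None:
        times = DEFAULT_SCHEDULE
    vals = traj.eval_internal(times)
    if np.any(vals < -NEG_TOL):
        raise IntegrationError("negative concentration beyond tolerance")
    vals = np.maximum(vals, 0.0)
    return SubjectSeries(
        time_min=np.asarray(times, dtype=float),
        glucose_mM=vals[0] / MGDL_PER_MM,
        insulin_pM=vals[1] * 10.0,
        glucagon_pM=vals[2],
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _breakpoints(params: ModelParameters, schedule: InfusionSchedule,
                 anchor: HysteresisAnchor, t_end: float) -> np.ndarray:
    """Restart times: infusion-block edges shifted by tau, the hysteresis
    switch and its delay images, and the ends of the constant history."""
    pts = {0.0, t_end}
    edges = np.arange(schedule.n_blocks + 1) * schedule.block_min
    for e in edges:
        pts.add(e + params.tau)
    for base in (anchor.t_hyst,):
        for shift in (0.0, params.tau1, params.tau2):
            pts.add(base + shift)
    for d in (params.tau, params.tau1, params.tau2):
        if d > 0:
            pts.add(d)
    arr = np.array(sorted(p for p in pts if 0.0 <= p <= t_end))
    return arr


def _min_positive_delay(params: ModelParameters) -> float:
    delays = [d for d in (params.tau1, params.tau2) if d > 0]
    return min(delays) if delays else np.inf


def _anchor_terms(params: ModelParameters, anchor: HysteresisAnchor,
                  continuity_corrected: bool):
    if params.variant is Variant.MODEL1_HILL:
        h_rise = h_fall = params.h
        C1 = params.psi_scale
    else:
        h_rise, h_fall = params.h1, params.h2
        C1 = c1_adjustment(params.h1, params.h2, params.K, anchor.G_hyst,
                           params.psi_scale)
    yshift = anchor.yshift(params.k1)
    if continuity_corrected:
        yshift -= math.exp(-params.k2 * anchor.G_hyst)
    return h_rise, h_fall, C1, yshift


def equilibrium_state(params: ModelParameters, G0_mM: float) -> SystemState:
    """Fasting steady state (internal units) for given fasting glucose."""
    I0, A0, _ = solve_equilibrium(params, G0_mM)
    return SystemState(t=0.0, G=G0_mM * MGDL_PER_MM, I=I0, A=A0)


def simulate(params: ModelParameters, schedule: InfusionSchedule,
             anchor: HysteresisAnchor, initial: SystemState,
             t_end: float = 240.0, method: str = "adaptive",
             dt: float = 0.25, rtol: float = 1e-8, atol: float = 1e-10,
             continuity_corrected: bool = False) -> Trajectory:
    """Integrate the delay system by the method of steps.

    ``anchor`` must be fixed before integration — from the measured
    glucose profile in fitting mode, or from rising-branch event
    detection (:func:`detect_anchor_forward`) in pure-forward mode.
    """
    if params.variant is Variant.MODEL2_HYSTERESIS and anchor is None:
        raise InvalidArgumentError("hysteresis variant requires an anchor")
    anchor = anchor or RISING_ONLY_ANCHOR
    y0 = np.array([initial.G, initial.I, initial.A], dtype=float)
    h_rise, h_fall, C1, yshift = _anchor_terms(params, anchor,
                                               continuity_corrected)
    rates = schedule.rates_mg_per_kg_min()
    bps = _breakpoints(params, schedule, anchor, t_end)
    cap = _min_positive_delay(params)

    if method == "rk4":
        step = min(dt, cap)
        grid = [np.array([0.0])]
        for t0, t1 in zip(bps[:-1], bps[1:]):
            nstep = max(1, int(math.ceil((t1 - t0) / step - 1e-12)))
            grid.append(np.linspace(t0, t1, nstep + 1)[1:])
        ts = np.concatenate(grid)
        Y, D = _integrate_rk4(
            ts, y0, params.SG, params.a1, params.a2, params.V, params.n1,
            params.n2, params.gamma1, params.gamma2, params.k1, params.k2,
            params.K, params.psi_scale, h_rise, h_fall, C1,
            anchor.t_hyst, yshift, params.tau, params.tau1, params.tau2,
            rates, schedule.block_min, schedule.t_end)
        if np.any(Y < -NEG_TOL):
            raise IntegrationError("negative state during integration")
        spline = CubicHermiteSpline(ts, Y, D, axis=1)
        return Trajectory(history=y0, t_start=-params.max_delay, t_end=t_end,
                          spline=spline,
                          meta={"method": "rk4", "dt": step, "n_nodes": ts.size})

    if method != "adaptive":
        raise InvalidArgumentError(f"unknown integration method {method!r}")

    rate = delayed_rate(build_infusion_rate(schedule), params.tau)
    segments = []
    seg_starts = []

    def g_lookup(s):
        """Delayed glucose (mg/dL) from completed segments or history."""
        if s <= 0:
            return y0[0]
        i = bisect.bisect_right(seg_starts, s) - 1
        i = max(0, min(i, len(segments) - 1))
        return segments[i][2](s)[0]

    def f(t, y):
        G, I, A = y
        gd1 = (g_lookup(t - params.tau1) if params.tau1 > 0 else G) / MGDL_PER_MM
        gd2 = (g_lookup(t - params.tau2) if params.tau2 > 0 else G) / MGDL_PER_MM
        gd1 = max(gd1, 0.0)
        gd2 = max(gd2, 0.0)
        if t < anchor.t_hyst:
            r = (gd1 / params.K) ** h_rise
            psi = params.psi_scale * r / (1.0 + r)
            phi = math.exp(-params.k1 * gd2)
        else:
            r = (gd1 / params.K) ** h_fall
            psi = C1 * r / (1.0 + r)
            phi = math.exp(-params.k2 * gd2) + yshift
        return [-(params.SG + params.a1 * I) * G + params.a2 * A
                + float(rate(t)) / params.V,
                -params.n1 * I + params.gamma1 * psi,
                -params.n2 * A + params.gamma2 * phi]

    # segment list: breakpoint intervals further capped by the least delay
    nfev = 0
    y = y0.copy()
    for t0, t1 in zip(bps[:-1], bps[1:]):
        nsub = max(1, int(math.ceil((t1 - t0) / cap - 1e-12))) \
            if np.isfinite(cap) else 1
        subs = np.linspace(t0, t1, nsub + 1)
        for s0, s1 in zip(subs[:-1], subs[1:]):
            sol = solve_ivp(f, (s0, s1), y, method="RK45", rtol=rtol,
                            atol=atol, dense_output=True)
            if not sol.success:
                raise IntegrationError(f"solver failed on [{s0}, {s1}]: "
                                       f"{sol.message}")
            nfev += sol.nfev
            segments.append((s0, s1, sol.sol))
            seg_starts.append(s0)
            y = sol.y[:, -1]
            if np.any(y < -NEG_TOL):
                raise IntegrationError("negative state during integration")
    return Trajectory(history=y0, t_start=-params.max_delay, t_end=t_end,
                      segments=segments,
                      meta={"method": "adaptive", "rtol": rtol, "atol": atol,
                            "nfev": nfev})


def detect_anchor_forward(params: ModelParameters, schedule: InfusionSchedule,
                          initial: SystemState, t_end: float = 240.0,
                          grid_min: float = 0.1, **kw) -> HysteresisAnchor:
    """Locate the glucose maximum of a pure-forward simulation.

    Runs the rising-branch-only model, takes the dense argmax of glucose,
    and returns the anchor (mM, min).  Resolves the anchor/solution
    circularity of forward simulation; fitting mode takes the anchor from
    measured data instead.
    """
    rising = params if params.variant is Variant.MODEL1_HILL else \
        params.with_updates(variant=Variant.MODEL1_HILL, h=params.h1,
                            h1=None, h2=None)
    traj = simulate(rising, schedule, RISING_ONLY_ANCHOR, initial,
                    t_end=t_end, **kw)
    tg = np.arange(0.0, t_end + grid_min / 2, grid_min)
    g = traj.eval_internal(tg)[0]
    i = int(np.argmax(g))
    return HysteresisAnchor(G_hyst=float(g[i]) / MGDL_PER_MM,
                            t_hyst=float(tg[i]))


def simulate_forward(params: ModelParameters, schedule: InfusionSchedule,
                     initial: SystemState, t_end: float = 240.0, **kw):
    """Forward simulation with self-detected anchor.

    Returns ``(trajectory, anchor)``.
    """
    anchor = detect_anchor_forward(params, schedule, initial, t_end=t_end,
                                   **kw)
    traj = simulate(params, schedule, anchor, initial, t_end=t_end, **kw)
    return traj, anchor


def substitute_and_simulate(base, param_overrides: Optional[dict] = None,
                            schedule: Optional[InfusionSchedule] = None,
                            allow_fixed_override: bool = False,
                            t_end: float = 240.0, **kw) -> Trajectory:
    """Counterfactual re-simulation of a fitted subject.

    ``base`` is a completed fit (anything exposing ``params``,
    ``schedule``, ``initial_state`` and ``anchor``).  Named parameter
    fields and/or the infusion schedule are replaced, everything else is
    held — the substitution experiments that swap one subject's glucose
    arrival profile or parameter subset into another's fit.
    """
    param_overrides = dict(param_overrides or {})
    fixed = {"SG", "n1", "n2", "K", "psi_scale", "V"}
    touched = fixed & set(param_overrides)
    if touched and not allow_fixed_override:
        raise InvalidArgumentError(
            f"overriding fixed constants {sorted(touched)} requires "
            "allow_fixed_override=True")
    params = base.params.with_updates(**param_overrides) if param_overrides \
        else base.params
    sched = schedule if schedule is not None else base.schedule
    return simulate(params, sched, base.anchor, base.initial_state,
                    t_end=t_end, **kw)
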