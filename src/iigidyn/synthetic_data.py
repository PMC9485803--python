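"""Synthetic IIGI subjects: infusion profiles, equilibrium-consistent
parameters, noiseless model trajectories and noisy sampled series.

The generator emulates the study conditions of the underlying IIGI
cohort: infusion profiles are bimodal and short for control subjects
(CS) and unimodal/prolonged for patients with type 2 diabetes (T2D),
with the oral-challenge-matched ceiling of 75 g total glucose; model
parameters are drawn within the published per-group cohort ranges; the
pre-infusion state is the model's fasting equilibrium; and sampled
series carry independent multiplicative Gaussian noise at the assay
coefficients of variation (glucose 2%, insulin 3%, glucagon 5.5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .infusion import InfusionSchedule, detect_hysteresis_anchor
from .model_core import (MGDL_PER_MM, HysteresisAnchor, InvalidArgumentError,
                         ModelParameters, SystemState, Variant,
                         hill_response, solve_equilibrium)
from .series import DEFAULT_SCHEDULE, SubjectSeries
from .simulator import (Trajectory, detect_anchor_forward, equilibrium_state,
                        sample_at, simulate, simulate_forward)
from .stats_compare import load_table_fixture

#: Published per-group parameter ranges (cohort summary table).  Delay
#: ranges start at 0: subjects without an observable delay are recorded
#: as 0.  h1/h2 ranges come from the hysteresis-variant per-subject tables.
GROUP_RANGES = {
    "CS": {
        "a1": (5.5e-5, 1.2e-3),
        "a2": (0.052, 0.59),
        "gamma1": (3.2, 21.0),
        "gamma2": (0.92, 8.1),
        "k1": (0.046, 0.48),
        "k2": (0.35, 0.55),
        "h": (1.3, 2.3),
        "h1": (0.94, 2.2),
        "h2": (1.4, 2.4),
        "tau": (0.0, 5.3),
        "tau1": (0.0, 12.0),
        "tau2": (0.0, 0.0),
    },
    "T2D": {
        "a1": (5.0e-5, 1.1e-4),
        "a2": (0.11, 0.50),
        "gamma1": (2.0, 10.0),
        "gamma2": (1.4, 8.6),
        "k1": (0.10, 0.23),
        "k2": (0.33, 0.60),
        "h": (1.0, 1.9),
        "h1": (0.9, 2.3),
        "h2": (0.90, 2.0),
        "tau": (0.0, 12.0),
        "tau1": (0.0, 45.0),
        "tau2": (0.0, 0.0),
    },
}

#: Fasting glucose draw ranges, mM (physiological convention: normal
#: fasting glycemia for CS, diabetic fasting range for T2D).
G0_RANGES = {"CS": (4.8, 6.0), "T2D": (7.0, 10.0)}

#: Total infused glucose draw ranges, g.  The IIGI total is the oral load
#: minus the incretin-mediated saving, so CS (large incretin effect) need
#: far less than the 75 g oral challenge; T2D approach the full load.
TOTAL_G_RANGES = {"CS": (25.0, 45.0), "T2D": (45.0, 75.0)}

OGTT_CEILING_G = 75.0

DEFAULT_NOISE_CVS = (0.02, 0.03, 0.055)


@dataclass
class GenConfig:
    """Generator settings (defaults are the study conditions)."""

    variant: Variant = Variant.MODEL1_HILL
    param_mode: str = "range_uniform"        # or "table_resample"
    baseline_mode: str = "equilibrium_first"  # or "a2_drawn"
    noise_cvs: tuple = DEFAULT_NOISE_CVS
    noise: bool = True
    weight_range: tuple = (75.0, 95.0)
    total_g_ceiling: float = OGTT_CEILING_G
    sample_times: np.ndarray = field(
        default_factory=lambda: DEFAULT_SCHEDULE.copy())
    dt: float = 0.1                           # truth-simulation step, min
    a2_equilibrium_bounds: tuple = (0.02, 2.0)
    max_attempts: int = 10


@dataclass
class SyntheticSubject:
    """One fully generated subject with its ground truth."""

    subject_id: str
    group: str
    params: ModelParameters
    G0_mM: float
    I0_pM: float
    A0_pM: float
    schedule: InfusionSchedule
    anchor: HysteresisAnchor
    noiseless: SubjectSeries
    noisy: SubjectSeries
    seed: int

    def truth_dict(self) -> dict:
        d = self.params.to_dict()
        d.update(subject_id=self.subject_id, group=self.group,
                 G0_mM=self.G0_mM, I0_pM=self.I0_pM, A0_pM=self.A0_pM,
                 weight_kg=self.schedule.weight_kg,
                 total_g=self.schedule.total_grams, seed=self.seed,
                 G_hyst_mM=self.anchor.G_hyst, t_hyst_min=self.anchor.t_hyst)
        return d


# ---------------------------------------------------------------------------
# infusion profiles
# ---------------------------------------------------------------------------

def gen_infusion_profile(group: str, total_g: float,
                         rng: np.random.Generator,
                         weight_kg: float = 85.0,
                         n_blocks: int = 16,
                         block_min: float = 15.0) -> InfusionSchedule:
    """Draw a group-shaped infusion schedule summing to ``total_g``.

    CS profiles are a mixture of two bumps (peaks near ~20 and ~65 min,
    done within ~2 h); T2D profiles are a single broad bump extending up
    to ~180 min.  Block grams are nonnegative and renormalized to the
    requested total.
    """
    if not (0 < total_g <= OGTT_CEILING_G + 1e-9):
        raise InvalidArgumentError(
            f"total_g must be in (0, {OGTT_CEILING_G}], got {total_g}")
    edges = np.arange(n_blocks + 1) * block_min
    if group == "CS":
        c1 = rng.uniform(15.0, 22.0)
        c2 = rng.uniform(60.0, 75.0)
        w1 = rng.uniform(0.38, 0.5)
        mass = (w1 * (norm.cdf(edges[1:], c1, 7.0) - norm.cdf(edges[:-1], c1, 7.0))
                + (1 - w1) * (norm.cdf(edges[1:], c2, 13.0)
                              - norm.cdf(edges[:-1], c2, 13.0)))
        mass[edges[:-1] >= 120.0] = 0.0   # CS infusions finish within ~2 h
    elif group == "T2D":
        c = rng.uniform(60.0, 90.0)
        sd = rng.uniform(35.0, 48.0)
        mass = norm.cdf(edges[1:], c, sd) - norm.cdf(edges[:-1], c, sd)
        mass[edges[:-1] >= 180.0] = 0.0   # prolonged but done by ~3 h
    else:
        raise InvalidArgumentError(f"unknown group {group!r}")
    grams = total_g * mass / mass.sum()
    return InfusionSchedule(grams_per_block=grams, weight_kg=weight_kg,
                            block_min=block_min)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def gen_subject_params(group: str, rng: np.random.Generator,
                       mode: str = "range_uniform",
                       variant: Variant = Variant.MODEL1_HILL
                       ) -> ModelParameters:
    """Draw model parameters for one subject.

    ``range_uniform`` draws each estimated/manual parameter uniformly
    within its group's published range; ``table_resample`` returns one of
    the published per-subject rows verbatim.  Fixed constants always take
    their literature values.
    """
    variant = Variant(variant)
    if group not in GROUP_RANGES:
        raise InvalidArgumentError(f"unknown group {group!r}")
    if mode == "range_uniform":
        r = GROUP_RANGES[group]
        def u(name):
            lo, hi = r[name]
            return float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        kw = dict(a1=u("a1"), a2=u("a2"), gamma1=u("gamma1"),
                  gamma2=u("gamma2"), k1=u("k1"), k2=u("k2"),
                  tau=u("tau"), tau1=u("tau1"), tau2=u("tau2"),
                  variant=variant)
        if variant is Variant.MODEL1_HILL:
            kw["h"] = u("h")
        else:
            kw["h1"], kw["h2"] = u("h1"), u("h2")
        return ModelParameters(**kw)
    if mode == "table_resample":
        key = f"{group.lower()}_{'model1' if variant is Variant.MODEL1_HILL else 'model2'}"
        df = load_table_fixture(key)
        row = df.iloc[int(rng.integers(len(df)))]
        kw = dict(a1=row.a1, a2=row.a2, gamma1=row.gamma1, gamma2=row.gamma2,
                  k1=row.k1, k2=row.k2, tau=row.tau, tau1=row.tau1,
                  variant=variant)
        if variant is Variant.MODEL1_HILL:
            kw["h"] = row.h
        else:
            kw["h1"], kw["h2"] = row.h1, row.h2
        return ModelParameters(**kw)
    raise InvalidArgumentError(f"unknown parameter mode {mode!r}")


def simulate_sampled(params: ModelParameters, schedule: InfusionSchedule,
                     initial: SystemState, sample_times=None,
                     dt: float = 0.1, max_iter: int = 8):
    """Simulate a subject and fix the hysteresis anchor at the
    sampled-glucose argmax.

    Forward event detection gives a first anchor from the dense
    rising-branch solution; the anchor is then iterated to the fixed
    point of "simulate, sample, take the raw-sample argmax" — the same
    anchor the estimation stage detects from measured data, so generated
    series and refits are mutually consistent.  A draw whose glucose
    maximum alternates between two branches (two near-equal peaks) has
    no fixed point and is rejected.  Returns
    ``(noiseless_series, anchor, trajectory)``.
    """
    if sample_times is None:
        sample_times = DEFAULT_SCHEDULE
    t_end = float(sample_times[-1])
    anchor = detect_anchor_forward(params, schedule, initial, t_end=t_end,
                                   method="rk4", dt=dt)
    for _ in range(max_iter):
        traj = simulate(params, schedule, anchor, initial, t_end=t_end,
                        method="rk4", dt=dt)
        series = sample_at(traj, sample_times)
        new = detect_hysteresis_anchor(series)
        if (abs(new.t_hyst - anchor.t_hyst) < 1e-9
                and abs(new.G_hyst - anchor.G_hyst) < 1e-12):
            return series, anchor, traj
        anchor = new
    raise InvalidArgumentError(
        "hysteresis anchor has no sample-grid fixed point (ambiguous "
        "glucose maximum); subject rejected")


def _adjust_g0_for_a2(params: ModelParameters) -> float:
    """Fasting glucose at which the drawn a2 closes the glucose balance."""
    def gap(g0):
        i0 = params.gamma1 * hill_response(g0, params.h_rising, params.K,
                                           params.psi_scale) / params.n1
        a0 = params.gamma2 * math.exp(-params.k1 * g0) / params.n2
        return (params.SG + params.a1 * i0) * g0 * MGDL_PER_MM - params.a2 * a0
    return brentq(gap, 0.5, 30.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# subjects and cohorts
# ---------------------------------------------------------------------------

def gen_subject(group: str, rng: np.random.Generator,
                config: Optional[GenConfig] = None,
                subject_id: str = "S1", seed: int = 0) -> SyntheticSubject:
    """Generate one complete synthetic subject.

    Parameters and fasting glucose are drawn; insulin and glucagon
    baselines come from the fasting equilibrium, with a2 derived so the
    pre-infusion state is stationary (default) or, in ``a2_drawn`` mode,
    a2 kept as drawn and the fasting glucose adjusted instead.  The
    noiseless series is the exact sampled model solution; the noisy
    series adds independent multiplicative Gaussian noise per analyte,
    truncated at zero.
    """
    config = config or GenConfig()
    last_err = None
    for _ in range(config.max_attempts):
        try:
            params = gen_subject_params(group, rng, config.param_mode,
                                        config.variant)
            if config.baseline_mode == "equilibrium_first":
                g0 = float(rng.uniform(*G0_RANGES[group]))
                i0, a0, a2_eq = solve_equilibrium(params, g0)
                lo, hi = config.a2_equilibrium_bounds
                if not (lo <= a2_eq <= hi):
                    raise InvalidArgumentError(
                        f"equilibrium a2={a2_eq:.3g} outside {lo}-{hi}")
                params = params.with_updates(a2=a2_eq)
            elif config.baseline_mode == "a2_drawn":
                g0 = _adjust_g0_for_a2(params)
                i0, a0, _ = solve_equilibrium(params, g0)
            else:
                raise InvalidArgumentError(
                    f"unknown baseline mode {config.baseline_mode!r}")
            weight = float(rng.uniform(*config.weight_range))
            total = float(rng.uniform(*TOTAL_G_RANGES[group]))
            total = min(total, config.total_g_ceiling)
            schedule = gen_infusion_profile(group, total, rng,
                                            weight_kg=weight)
            initial = SystemState(t=0.0, G=g0 * MGDL_PER_MM, I=i0, A=a0)
            noiseless, anchor, _ = simulate_sampled(
                params, schedule, initial, config.sample_times, dt=config.dt)
            noiseless.subject_id = subject_id
            break
        except (InvalidArgumentError, ValueError) as exc:
            last_err = exc
    else:
        raise InvalidArgumentError(
            f"could not generate subject after {config.max_attempts} "
            f"attempts: {last_err}")

    if config.noise:
        cvs = config.noise_cvs
        noisy = SubjectSeries(
            time_min=noiseless.time_min.copy(),
            glucose_mM=np.maximum(
                0.0, noiseless.glucose_mM *
                (1 + cvs[0] * rng.standard_normal(len(noiseless)))),
            insulin_pM=np.maximum(
                0.0, noiseless.insulin_pM *
                (1 + cvs[1] * rng.standard_normal(len(noiseless)))),
            glucagon_pM=np.maximum(
                0.0, noiseless.glucagon_pM *
                (1 + cvs[2] * rng.standard_normal(len(noiseless)))),
            subject_id=subject_id,
        )
    else:
        noisy = noiseless
    return SyntheticSubject(
        subject_id=subject_id, group=group, params=params, G0_mM=g0,
        I0_pM=i0 * 10.0, A0_pM=a0, schedule=schedule, anchor=anchor,
        noiseless=noiseless, noisy=noisy, seed=seed)


def gen_cohort(n_cs: int, n_t2d: int, seed: int,
               config: Optional[GenConfig] = None):
    """Deterministic cohort from one master seed.

    Per-subject seeds are derived from the master seed by counter, so the
    cohort is reproducible subject-by-subject.  Returns
    ``(subjects, manifest)`` where the manifest records seeds and true
    parameters for recovery scoring.
    """
    config = config or GenConfig()
    master = np.random.default_rng(seed)
    subjects = []
    specs = [("CS", i) for i in range(n_cs)] + \
            [("T2D", i) for i in range(n_t2d)]
    for group, i in specs:
        sub_seed = int(master.integers(2 ** 31))
        rng = np.random.default_rng(sub_seed)
        sid = f"{group}{i + 1:02d}"
        subjects.append(gen_subject(group, rng, config, subject_id=sid,
                                    seed=sub_seed))
    manifest = {
        "master_seed": seed,
        "n_cs": n_cs,
        "n_t2d": n_t2d,
        "variant": Variant(config.variant).value,
        "subjects": [s.truth_dict() for s in subjects],
    }
    return subjects, manifest
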