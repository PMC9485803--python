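"""Self-validation studies: parameter recovery on synthetic cohorts and
AICc model-selection behavior.

These drive the package's reproducibility checks: every study generates
its own synthetic subjects (the ground truth), runs the full fitting
pipeline on them, and scores the estimates against the truth manifest.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import FitConfig, fit_model
from .model_core import MGDL_PER_MM, SystemState, Variant
from .series import SubjectSeries
from .stats_compare import compare_models
from .synthetic_data import (GenConfig, SyntheticSubject, gen_cohort,
                             gen_subject, simulate_sampled)

#: Free parameters scored in recovery studies (Hill variant).
RECOVERY_PARAMS = ("a1", "a2", "gamma1", "gamma2", "k1", "h")


def _fit_config_for(subject: SyntheticSubject, variant: Variant,
                    **kw) -> FitConfig:
    """Fit configuration with the subject's true manual parameters held
    (the delays and k2 are manually adjusted, not estimated)."""
    manual = {"tau": subject.params.tau, "tau1": subject.params.tau1,
              "tau2": subject.params.tau2, "k2": subject.params.k2}
    return FitConfig(variant=variant, manual=manual, group=subject.group,
                     **kw)


def _add_noise(series: SubjectSeries, cvs, rng) -> SubjectSeries:
    """Independent multiplicative Gaussian noise per analyte, floored at 0."""
    n = len(series)
    return SubjectSeries(
        time_min=series.time_min.copy(),
        glucose_mM=np.maximum(0.0, series.glucose_mM *
                              (1 + cvs[0] * rng.standard_normal(n))),
        insulin_pM=np.maximum(0.0, series.insulin_pM *
                              (1 + cvs[1] * rng.standard_normal(n))),
        glucagon_pM=np.maximum(0.0, series.glucagon_pM *
                               (1 + cvs[2] * rng.standard_normal(n))),
        subject_id=series.subject_id,
    )


def recovery_study(seed: int, n_subjects: int = 20, group: str = "CS",
                   noise: bool = True, n_starts: int = 1,
                   dt: float = 0.1) -> pd.DataFrame:
    """Fit a synthetic cohort and score relative errors against truth.

    Returns a frame with one row per subject and one column of relative
    errors ``|est - true| / true`` per free parameter.
    """
    gen = GenConfig(noise=noise)
    n_cs = n_subjects if group == "CS" else 0
    n_t2d = n_subjects if group == "T2D" else 0
    subjects, _ = gen_cohort(n_cs, n_t2d, seed, gen)
    rows = []
    # noiseless refits are a consistency check: polish to machine-level
    tol = {} if noise else {"ftol": 1e-14, "xtol": 1e-14}
    for s in subjects:
        cfg = _fit_config_for(s, Variant.MODEL1_HILL, n_starts=n_starts,
                              dt=dt, seed=seed, **tol)
        data = s.noisy if noise else s.noiseless
        fit = fit_model(data, s.schedule, cfg)
        truth = s.params.to_dict()
        row = {name: abs(fit.estimates[name] - truth[name]) / abs(truth[name])
               for name in RECOVERY_PARAMS}
        row["subject_id"] = s.subject_id
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def median_recovery_errors(errors: pd.DataFrame) -> dict:
    """Median relative error per parameter, as fractions."""
    return {c: float(errors[c].median()) for c in errors.columns}


def _hysteresis_subject(rep: int, sub_seed: int, gen: GenConfig,
                        h1: float, h2: float) -> SyntheticSubject:
    """Synthetic subject re-simulated under hysteresis truth (h1, h2).

    Draws whose re-simulated glucose maximum is ambiguous (no anchor
    fixed point) are rejected and redrawn, as in the generator.
    """
    from .model_core import InvalidArgumentError

    rng = np.random.default_rng(sub_seed)
    last_err = None
    for _ in range(10):
        base = gen_subject("CS", rng,
                           replace(gen, variant=Variant.MODEL1_HILL),
                           subject_id=f"R{rep + 1:02d}", seed=sub_seed)
        params = base.params.with_updates(variant=Variant.MODEL2_HYSTERESIS,
                                          h=None, h1=h1, h2=h2)
        initial = SystemState(t=0.0, G=base.G0_mM * MGDL_PER_MM,
                              I=base.I0_pM / 10.0, A=base.A0_pM)
        try:
            noiseless, anchor, _ = simulate_sampled(
                params, base.schedule, initial, gen.sample_times, dt=gen.dt)
        except InvalidArgumentError as exc:
            last_err = exc
            continue
        noiseless.subject_id = base.subject_id
        noisy = _add_noise(noiseless, gen.noise_cvs, rng) if gen.noise \
            else noiseless
        return replace(base, params=params, anchor=anchor,
                       noiseless=noiseless, noisy=noisy)
    raise InvalidArgumentError(
        f"could not generate hysteresis subject: {last_err}")


def model_selection_study(seed: int, n_reps: int = 20,
                          truth_variant: Variant = Variant.MODEL2_HYSTERESIS,
                          h1: float = 1.0, h2: float = 2.5,
                          noise_scale: float = 0.25,
                          n_starts: int = 1, dt: float = 0.1) -> pd.DataFrame:
    """AICc comparison of both variants over replicated synthetic subjects.

    Subjects are generated under ``truth_variant`` (hysteresis truth uses
    the given ``h1``/``h2``; Hill truth draws h within the cohort range)
    at ``noise_scale`` times the assay CVs.  Each replicate is fit with
    both variants and compared by AICc.  Returns one row per replicate
    with the signed difference ``AICc(model 1) - AICc(model 2)`` and the
    preferred model.
    """
    truth_variant = Variant(truth_variant)
    cvs = tuple(noise_scale * c for c in GenConfig().noise_cvs)
    gen = GenConfig(noise_cvs=cvs)
    rows = []
    master = np.random.default_rng(seed)
    for rep in range(n_reps):
        sub_seed = int(master.integers(2 ** 31))
        if truth_variant is Variant.MODEL2_HYSTERESIS:
            s = _hysteresis_subject(rep, sub_seed, gen, h1, h2)
        else:
            rng = np.random.default_rng(sub_seed)
            s = gen_subject("CS", rng, gen, subject_id=f"R{rep + 1:02d}",
                            seed=sub_seed)
        fit1 = fit_model(s.noisy, s.schedule,
                         _fit_config_for(s, Variant.MODEL1_HILL,
                                         n_starts=n_starts, dt=dt,
                                         seed=sub_seed))
        fit2 = fit_model(s.noisy, s.schedule,
                         _fit_config_for(s, Variant.MODEL2_HYSTERESIS,
                                         n_starts=n_starts, dt=dt,
                                         seed=sub_seed))
        cmp = compare_models(fit1, fit2)
        rows.append({"replicate": s.subject_id,
                     "delta_aicc": cmp.delta_aicc,
                     "preferred": cmp.preferred,
                     "model2_preferred": cmp.delta_aicc > 0})
    return pd.DataFrame(rows).set_index("replicate")
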