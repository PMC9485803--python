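"""File formats, run configuration and report plumbing.

All on-disk formats are plain text: subject series and infusion records
as CSV with unit-bearing column names, the cohort truth manifest as
JSON, and run configuration as YAML.  Column units are encoded in the
headers (``glucose_mM``, ``insulin_pM``, ...) so unit drift is visible
at the file boundary, which is the only place conversions happen.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .infusion import InfusionSchedule
from .model_core import (HysteresisAnchor, ModelParameters, SystemState,
                         MGDL_PER_MM)
from .series import SubjectSeries
from .simulator import Trajectory

SERIES_COLUMNS = ["time_min", "glucose_mM", "insulin_pM", "glucagon_pM"]


class SchemaError(ValueError):
    """A data file violates its schema."""


# ---------------------------------------------------------------------------
# subject series
# ---------------------------------------------------------------------------

def read_subject_series(path) -> SubjectSeries:
    """Read a subject series CSV (columns ``time_min, glucose_mM,
    insulin_pM, glucagon_pM``), validating monotone times, nonnegative
    concentrations and the presence of baseline (t <= 0) rows."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 2  # 1-based incl. header
        raise SchemaError(f"{path}: times not strictly increasing at row {row}")
    for c in SERIES_COLUMNS[1:]:
        v = df[c].to_numpy(dtype=float)
        if np.any(v < 0) or np.any(~np.isfinite(v)):
            row = int(np.argmax((v < 0) | ~np.isfinite(v))) + 2
            raise SchemaError(f"{path}: invalid {c} at row {row}")
    if not np.any(t <= 0):
        raise SchemaError(f"{path}: no baseline (time_min <= 0) rows")
    return SubjectSeries(time_min=t,
                         glucose_mM=df["glucose_mM"].to_numpy(dtype=float),
                         insulin_pM=df["insulin_pM"].to_numpy(dtype=float),
                         glucagon_pM=df["glucagon_pM"].to_numpy(dtype=float),
                         subject_id=Path(str(path)).stem)


def write_subject_series(series: SubjectSeries, path) -> None:
    pd.DataFrame({
        "time_min": series.time_min,
        "glucose_mM": series.glucose_mM,
        "insulin_pM": series.insulin_pM,
        "glucagon_pM": series.glucagon_pM,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# infusion records
# ---------------------------------------------------------------------------

def read_infusion_csv(path, weight_kg: float) -> InfusionSchedule:
    """Read an infusion record (columns ``block_start_min, grams``)."""
    df = pd.read_csv(path, comment="#")
    for c in ("block_start_min", "grams"):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")
    starts = df["block_start_min"].to_numpy(dtype=float)
    widths = np.diff(starts)
    if starts.size > 1 and not np.allclose(widths, widths[0]):
        raise SchemaError(f"{path}: blocks are not uniform width")
    block_min = float(widths[0]) if starts.size > 1 else 15.0
    if starts.size and starts[0] != 0:
        raise SchemaError(f"{path}: first block must start at 0")
    return InfusionSchedule(grams_per_block=df["grams"].to_numpy(dtype=float),
                            weight_kg=weight_kg, block_min=block_min)


def write_infusion_csv(schedule: InfusionSchedule, path) -> None:
    pd.DataFrame({
        "block_start_min": schedule.block_start_times,
        "grams": schedule.grams_per_block,
    }).to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path, dt: float = 1.0) -> None:
    """Export a trajectory densely sampled every ``dt`` min, data units."""
    t = np.arange(0.0, traj.t_end + dt / 2, dt)
    vals = traj.eval_internal(t)
    pd.DataFrame({
        "time_min": t,
        "glucose_mM": vals[0] / MGDL_PER_MM,
        "insulin_pM": vals[1] * 10.0,
        "glucagon_pM": vals[2],
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable pipeline configuration; unspecified fields resolve to
    the documented defaults (the study's values)."""

    seed: int = 0
    variant: str = "model1_hill"
    weighting: str = "cv_weighted"
    cvs: tuple = (0.02, 0.03, 0.055)
    manual: dict = field(default_factory=lambda: {
        "tau": 0.0, "tau1": 0.0, "tau2": 0.0, "k2": 0.5})
    fixed_overrides: dict = field(default_factory=dict)
    n_starts: int = 5
    integrator: str = "rk4"
    dt: float = 0.1
    rounding_sig_figs: int = 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cvs"] = list(self.cvs)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.cvs = tuple(cfg.cvs)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# fit reports and manifests
# ---------------------------------------------------------------------------

def fit_report_dict(fit, config_hash: str = "") -> dict:
    """JSON-serializable per-subject fit report."""
    return {
        "variant": fit.params.variant.value,
        "estimates": fit.estimates,
        "se": fit.se,
        "pvalues": fit.pvalues,
        "fixed": fit.fixed,
        "manual": fit.manual,
        "rss": fit.rss,
        "adj_r2": fit.adj_r2,
        "aicc": fit.aicc,
        "n": fit.n,
        "p": fit.p,
        "converged": fit.converged,
        "weighting": fit.weighting,
        "data_hash": fit.data_hash,
        "anchor": {"G_hyst_mM": fit.anchor.G_hyst,
                   "t_hyst_min": fit.anchor.t_hyst},
        "initial_state": {"G_mgdl": fit.initial_state.G,
                          "I_10pM": fit.initial_state.I,
                          "A_pM": fit.initial_state.A},
        "schedule": {"grams_per_block": list(map(float, fit.schedule.grams_per_block)),
                     "weight_kg": fit.schedule.weight_kg,
                     "block_min": fit.schedule.block_min},
        "config_hash": config_hash,
    }


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_cohort(subjects, manifest: dict, outdir) -> None:
    """Write a generated cohort: per-subject noisy/noiseless series and
    infusion CSVs plus the truth manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for s in subjects:
        write_subject_series(s.noisy, out / f"{s.subject_id}_series.csv")
        write_subject_series(s.noiseless,
                             out / f"{s.subject_id}_series_noiseless.csv")
        write_infusion_csv(s.schedule, out / f"{s.subject_id}_infusion.csv")
        meta_rows.append({"subject_id": s.subject_id, "group": s.group,
                          "weight_kg": s.schedule.weight_kg})
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)
    write_json(manifest, out / "manifest.json")
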