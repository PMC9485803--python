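"""Sampled hormone time series for one subject.

Data units are the experiment's: glucose mM, insulin pM, glucagon pM;
time in minutes relative to the start of the infusion.  The default
sampling schedule is the IIGI blood-draw schedule (three baseline draws
at -15, -10 and 0 min, then 17 post-infusion draws to 240 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Blood-sampling schedule of the underlying IIGI protocol, min.
DEFAULT_SCHEDULE = np.array([
    -15.0, -10.0, 0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0,
    40.0, 45.0, 50.0, 60.0, 70.0, 90.0, 120.0, 150.0, 180.0, 240.0,
])

ANALYTES = ("glucose", "insulin", "glucagon")


class SeriesError(ValueError):
    """Malformed subject series."""


@dataclass
class SubjectSeries:
    """Glucose/insulin/glucagon concentrations sampled over an experiment."""

    time_min: np.ndarray
    glucose_mM: np.ndarray
    insulin_pM: np.ndarray
    glucagon_pM: np.ndarray
    subject_id: Optional[str] = None

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.glucose_mM = np.asarray(self.glucose_mM, dtype=float)
        self.insulin_pM = np.asarray(self.insulin_pM, dtype=float)
        self.glucagon_pM = np.asarray(self.glucagon_pM, dtype=float)
        n = self.time_min.size
        for name in ("glucose_mM", "insulin_pM", "glucagon_pM"):
            if getattr(self, name).size != n:
                raise SeriesError(f"{name} length differs from time_min")
        if n and np.any(np.diff(self.time_min) <= 0):
            row = int(np.argmax(np.diff(self.time_min) <= 0)) + 1
            raise SeriesError(f"times not strictly increasing at row {row}")

    def __len__(self):
        return self.time_min.size

    @property
    def n_observations(self) -> int:
        """Total fitted observations across the three analytes."""
        return 3 * len(self)

    def analyte(self, name: str) -> np.ndarray:
        return {"glucose": self.glucose_mM, "insulin": self.insulin_pM,
                "glucagon": self.glucagon_pM}[name]

    def baseline_means(self):
        """Mean of the pre-infusion (t <= 0) samples per analyte, in data
        units (glucose mM, insulin pM, glucagon pM)."""
        mask = self.time_min <= 0
        if not mask.any():
            raise SeriesError("series has no baseline (t <= 0) samples")
        return (float(self.glucose_mM[mask].mean()),
                float(self.insulin_pM[mask].mean()),
                float(self.glucagon_pM[mask].mean()))

    def stacked(self) -> np.ndarray:
        """Concatenated values in fixed analyte order (glucose, insulin,
        glucagon), each ordered by time."""
        return np.concatenate([self.glucose_mM, self.insulin_pM,
                               self.glucagon_pM])
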