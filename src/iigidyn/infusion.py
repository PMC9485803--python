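"""Exogenous glucose arrival: 15-min infusion blocks -> piecewise-constant
rate function, the infusion delay, and hysteresis-anchor detection.

The IIGI protocol records the grams of glucose infused in each 15-min
block; the average rate over a block approximates the actual pump rate
(which was adjusted every 5 min).  The plasma arrival rate on block *i* is

    R = grams_i / 15 min * 1000 / weight    [mg/(kg min)]
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model_core import InvalidArgumentError, mgdl_to_mM, HysteresisAnchor
from .series import SubjectSeries, SeriesError

#: Standard block width of the infusion record, min.
DEFAULT_BLOCK_MIN = 15.0


@dataclass(frozen=True)
class InfusionSchedule:
    """Grams of glucose infused per block plus subject body weight."""

    grams_per_block: np.ndarray
    weight_kg: float
    block_min: float = DEFAULT_BLOCK_MIN

    def __post_init__(self):
        object.__setattr__(self, "grams_per_block",
                           np.asarray(self.grams_per_block, dtype=float))
        if np.any(self.grams_per_block < 0):
            raise InvalidArgumentError("block grams must be nonnegative")
        if not (self.weight_kg > 0):
            raise InvalidArgumentError("weight must be strictly positive")
        if not (self.block_min > 0):
            raise InvalidArgumentError("block width must be strictly positive")

    @property
    def n_blocks(self) -> int:
        return self.grams_per_block.size

    @property
    def t_end(self) -> float:
        """End of the infusion record, min."""
        return self.n_blocks * self.block_min

    @property
    def block_start_times(self) -> np.ndarray:
        return np.arange(self.n_blocks) * self.block_min

    @property
    def total_grams(self) -> float:
        return float(self.grams_per_block.sum())

    def rates_mg_per_kg_min(self) -> np.ndarray:
        """Arrival rate on each block, mg/(kg min)."""
        return self.grams_per_block / self.block_min * 1000.0 / self.weight_kg


def build_infusion_rate(schedule: InfusionSchedule) -> Callable:
    """Piecewise-constant arrival-rate function ``t -> R`` in mg/(kg min).

    Right-continuous at block boundaries; zero outside ``[0, t_end)``.
    """
    rates = schedule.rates_mg_per_kg_min()
    width = schedule.block_min
    t_end = schedule.t_end

    def rate(t):
        t = np.asarray(t, dtype=float)
        inside = (t >= 0) & (t < t_end)
        idx = np.clip((t // width).astype(int), 0, schedule.n_blocks - 1)
        out = np.where(inside, rates[idx], 0.0)
        return out if out.ndim else float(out)

    return rate


def delayed_rate(rate_fn: Callable, tau: float) -> Callable:
    """Shift a rate function by the circulation delay: ``t -> R(t - tau)``."""
    if tau < 0:
        raise InvalidArgumentError("tau must be >= 0")
    if tau == 0:
        return rate_fn

    def shifted(t):
        return rate_fn(np.asarray(t, dtype=float) - tau)

    return shifted


def detect_hysteresis_anchor(series: SubjectSeries) -> HysteresisAnchor:
    """Locate the glucose-curve maximum from measured samples.

    The anchor is the raw-sample argmax of glucose over ``t >= 0``; ties
    are broken toward the earliest time.
    """
    mask = series.time_min >= 0
    if mask.sum() < 3:
        raise SeriesError("need at least 3 post-zero samples to locate the "
                          "glucose maximum")
    t = series.time_min[mask]
    g = series.glucose_mM[mask]
    i = int(np.argmax(g))  # argmax returns the first maximum: earliest time
    return HysteresisAnchor(G_hyst=float(g[i]), t_hyst=float(t[i]))
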