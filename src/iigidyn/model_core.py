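"""Core model: symbols, unit conventions, dose-response functions and the
right-hand side of the coupled glucose-insulin-glucagon delay system.

The model tracks three plasma states during an isoglycemic intravenous
glucose infusion (IIGI):

* ``G`` — glucose, carried internally in mg/dL (the unit in which the
  glucagon-action constant ``a2`` and the infusion term ``R/V`` are
  expressed),
* ``I`` — insulin, carried internally in units of 10 pM (so that ``a1``
  and ``gamma1`` match their conventional table scales),
* ``A`` — glucagon, in pM.

Dose-response functions take glucose in mM (the unit of the Hill half-max
``K`` = 17 mM and the exponential constants ``k1``, ``k2``); the fixed
conversion is 18.016 mg/dL per mM.  All conversions to and from data units
happen at the I/O boundary only.

Dynamics::

    dG/dt = -(SG + a1*I)*G + a2*A + R(t - tau)/V
    dI/dt = -n1*I + gamma1 * psi(G(t - tau1))
    dA/dt = -n2*A + gamma2 * phi(G(t - tau2))

``psi`` is the glucose-dependent insulin secretion drive: a single Hill
function (variant ``model1_hill``) or a two-branch hysteretic Hill pair
switching at the glucose-curve maximum (variant ``model2_hysteresis``).
``phi`` is the glucagon secretion drive: ``exp(-k1*G)`` while glucose is
rising and ``exp(-k2*G) + yshift`` after the maximum, with
``yshift = exp(-k1*G_hyst)`` capturing the persistent post-challenge
suppression of glucagon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from typing import Optional

import numpy as np

#: mg/dL per mM of glucose (molar mass 180.16 g/mol).
MGDL_PER_MM = 18.016

#: Literature values of the constants that are never estimated.
FIXED_DEFAULTS = {
    "SG": 0.014,      # glucose-dependent glucose clearance, 1/min
    "n1": 0.14,       # insulin degradation, 1/min
    "n2": 0.08,       # glucagon degradation, 1/min
    "K": 17.0,        # Hill half-max glucose, mM (islet dose-response)
    "psi_scale": 1.5, # insulin dose-response prefactor, dimensionless
    "V": 1.35,        # glucose distribution volume, dL/kg
}


class Variant(str, Enum):
    """Insulin dose-response variant."""

    MODEL1_HILL = "model1_hill"
    MODEL2_HYSTERESIS = "model2_hysteresis"


class InvalidArgumentError(ValueError):
    """An argument violates a model precondition."""


class ConfigurationError(ValueError):
    """Inconsistent model configuration (e.g. missing hysteresis anchor)."""


class DegenerateEquilibriumError(ValueError):
    """Equilibrium algebra has no positive solution."""


def mM_to_mgdl(g_mM):
    """Convert glucose mM -> mg/dL."""
    return np.asarray(g_mM, dtype=float) * MGDL_PER_MM


def mgdl_to_mM(g_mgdl):
    """Convert glucose mg/dL -> mM."""
    return np.asarray(g_mgdl, dtype=float) / MGDL_PER_MM


@dataclass(frozen=True)
class HysteresisAnchor:
    """The glucose-curve maximum at which both dose-response functions
    switch branch.

    Attributes
    ----------
    G_hyst : float
        Glucose at the curve maximum, mM.
    t_hyst : float
        Time of the maximum, min.
    """

    G_hyst: float
    t_hyst: float

    def __post_init__(self):
        if not (self.G_hyst > 0):
            raise InvalidArgumentError(f"G_hyst must be positive, got {self.G_hyst}")
        if not np.isfinite(self.t_hyst):
            raise InvalidArgumentError("t_hyst must be finite")

    def yshift(self, k1: float) -> float:
        """Post-maximum glucagon-drive offset, ``exp(-k1 * G_hyst)``."""
        return math.exp(-k1 * self.G_hyst)


#: Anchor placed beyond any experiment: the system never leaves the rising
#: branch.  Used for pure-forward anchor detection.
RISING_ONLY_ANCHOR = HysteresisAnchor(G_hyst=1e6, t_hyst=1e18)


@dataclass(frozen=True)
class ModelParameters:
    """All symbols of the model, partitioned into estimated, manually
    adjusted, and fixed sets.

    Units follow the parameter-table conventions: ``a1`` in (10 pM min)^-1,
    ``a2`` in mg/dL (pM min)^-1, ``gamma1`` in 10 pM/min, ``gamma2`` in
    pM/min, ``k1``/``k2`` in mM^-1, delays in min.
    """

    # estimated
    a1: float = 5e-4
    a2: float = 0.25
    gamma1: float = 9.0
    gamma2: float = 3.0
    k1: float = 0.26
    h: Optional[float] = None
    h1: Optional[float] = None
    h2: Optional[float] = None
    # manually adjusted
    k2: float = 0.5
    tau: float = 0.0
    tau1: float = 0.0
    tau2: float = 0.0
    # fixed (literature values; overridable only deliberately)
    SG: float = FIXED_DEFAULTS["SG"]
    n1: float = FIXED_DEFAULTS["n1"]
    n2: float = FIXED_DEFAULTS["n2"]
    K: float = FIXED_DEFAULTS["K"]
    psi_scale: float = FIXED_DEFAULTS["psi_scale"]
    V: float = FIXED_DEFAULTS["V"]
    variant: Variant = Variant.MODEL1_HILL

    def __post_init__(self):
        object.__setattr__(self, "variant", Variant(self.variant))
        positive = ["a1", "a2", "gamma1", "gamma2", "k1", "k2",
                    "SG", "n1", "n2", "K", "psi_scale", "V"]
        for name in positive:
            v = getattr(self, name)
            if not (v > 0):
                raise InvalidArgumentError(f"{name} must be strictly positive, got {v}")
        for name in ("tau", "tau1", "tau2"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.variant is Variant.MODEL1_HILL:
            if self.h is None:
                raise ConfigurationError("model1_hill requires h")
            if self.h1 is not None or self.h2 is not None:
                raise ConfigurationError("model1_hill must not set h1/h2")
            if not self.h > 0:
                raise InvalidArgumentError("h must be strictly positive")
        else:
            if self.h1 is None or self.h2 is None:
                raise ConfigurationError("model2_hysteresis requires h1 and h2")
            if self.h is not None:
                raise ConfigurationError("model2_hysteresis must not set h")
            if not (self.h1 > 0 and self.h2 > 0):
                raise InvalidArgumentError("h1, h2 must be strictly positive")

    # -- convenience ----------------------------------------------------

    @property
    def h_rising(self) -> float:
        """Hill coefficient on the rising-glucose branch."""
        return self.h if self.variant is Variant.MODEL1_HILL else self.h1

    @property
    def h_falling(self) -> float:
        """Hill coefficient on the falling-glucose branch."""
        return self.h if self.variant is Variant.MODEL1_HILL else self.h2

    @property
    def max_delay(self) -> float:
        return max(self.tau, self.tau1, self.tau2)

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with named fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["variant"] = self.variant.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass(frozen=True)
class SystemState:
    """Model state at one instant: ``t`` min, ``G`` mg/dL (internal),
    ``I`` 10 pM (internal), ``A`` pM."""

    t: float
    G: float
    I: float
    A: float


# ---------------------------------------------------------------------------
# dose-response functions
# ---------------------------------------------------------------------------

def hill_response(G_mM, h: float, K: float = FIXED_DEFAULTS["K"],
                  psi_scale: float = FIXED_DEFAULTS["psi_scale"]):
    """Sigmoidal glucose-dependent insulin secretion drive.

    ``psi = psi_scale * G^h / (K^h + G^h)``, bounded in ``[0, psi_scale)``
    and monotone nondecreasing in ``G``.
    """
    G = np.asarray(G_mM, dtype=float)
    if np.any(G < 0):
        raise InvalidArgumentError("glucose must be nonnegative")
    if not (h > 0 and K > 0):
        raise InvalidArgumentError("h and K must be strictly positive")
    # (G/K)^h form avoids overflow for large G
    r = (G / K) ** h
    out = psi_scale * r / (1.0 + r)
    return out if out.ndim else float(out)


def c1_adjustment(h1: float, h2: float, K: float, G_hyst: float,
                  psi_scale: float = FIXED_DEFAULTS["psi_scale"]) -> float:
    """Prefactor making the falling-branch Hill curve meet the rising one
    at the hysteresis point.

    ``C1 = psi_scale * Hill(G_hyst; h1) / Hill_unit(G_hyst; h2)`` where
    ``Hill_unit = G^h2/(K^h2+G^h2)``.
    """
    if not (h1 > 0 and h2 > 0 and K > 0 and G_hyst > 0):
        raise InvalidArgumentError("all arguments must be strictly positive")
    if h1 == h2:  # branches identical: exact, not up to roundoff
        return psi_scale
    r1 = (G_hyst / K) ** h1
    r2 = (G_hyst / K) ** h2
    return psi_scale * (r1 / (1.0 + r1)) * ((1.0 + r2) / r2)


def insulin_dose_response(G_mM, t: float, params: ModelParameters,
                          anchor: Optional[HysteresisAnchor] = None):
    """Insulin secretion drive ``psi(G)`` for either model variant.

    Under the hysteresis variant the rising Hill curve (coefficient
    ``h1``) applies for ``t < t_hyst`` and the adjusted falling curve
    (coefficient ``h2``, prefactor ``C1``) for ``t >= t_hyst``; the two
    branches agree at ``(G_hyst, t_hyst)`` by construction of ``C1``.
    """
    if params.variant is Variant.MODEL1_HILL:
        return hill_response(G_mM, params.h, params.K, params.psi_scale)
    if anchor is None:
        raise ConfigurationError("model2_hysteresis requires a hysteresis anchor")
    if t < anchor.t_hyst:
        return hill_response(G_mM, params.h1, params.K, params.psi_scale)
    c1 = c1_adjustment(params.h1, params.h2, params.K, anchor.G_hyst,
                       params.psi_scale)
    return hill_response(G_mM, params.h2, params.K, psi_scale=c1)


def glucagon_dose_response(G_mM, t: float, k1: float, k2: float,
                           anchor: HysteresisAnchor,
                           continuity_corrected: bool = False):
    """Glucagon secretion drive ``phi(G)``.

    ``exp(-k1*G)`` while glucose rises; after the glucose maximum the
    drive recovers along ``exp(-k2*G) + yshift`` with
    ``yshift = exp(-k1*G_hyst)``.  As printed, the two branches differ by
    ``exp(-k2*G_hyst)`` at the switch; ``continuity_corrected=True``
    subtracts that term from ``yshift`` to make ``phi`` continuous.
    """
    if not (k1 > 0 and k2 > 0):
        raise InvalidArgumentError("k1, k2 must be strictly positive")
    G = np.asarray(G_mM, dtype=float)
    if np.any(G < 0):
        raise InvalidArgumentError("glucose must be nonnegative")
    if anchor is None:
        raise ConfigurationError("glucagon dose-response requires an anchor")
    if t < anchor.t_hyst:
        out = np.exp(-k1 * G)
    else:
        yshift = anchor.yshift(k1)
        if continuity_corrected:
            yshift -= math.exp(-k2 * anchor.G_hyst)
        out = np.exp(-k2 * G) + yshift
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# right-hand side and equilibrium
# ---------------------------------------------------------------------------

def rhs(state: SystemState, G_delayed_tau1_mM: float, G_delayed_tau2_mM: float,
        R_delayed: float, params: ModelParameters,
        anchor: Optional[HysteresisAnchor] = None,
        continuity_corrected: bool = False):
    """Time derivatives ``(dG/dt, dI/dt, dA/dt)`` of the coupled system.

    Pure function of its arguments; the delayed glucose values (mM) and
    the delayed infusion rate (mg/(kg min)) are supplied by the caller's
    history mechanism.  ``G`` is in mg/dL, ``I`` in 10 pM, ``A`` in pM.
    """
    psi = insulin_dose_response(G_delayed_tau1_mM, state.t, params, anchor)
    phi = glucagon_dose_response(G_delayed_tau2_mM, state.t, params.k1,
                                 params.k2, anchor or RISING_ONLY_ANCHOR,
                                 continuity_corrected)
    dG = -(params.SG + params.a1 * state.I) * state.G + params.a2 * state.A \
        + R_delayed / params.V
    dI = -params.n1 * state.I + params.gamma1 * psi
    dA = -params.n2 * state.A + params.gamma2 * phi
    return dG, dI, dA


def solve_equilibrium(params: ModelParameters, G0_mM: float):
    """Fasting steady state consistent with the model at zero infusion.

    Returns ``(I0, A0, a2_eq)``: insulin (10 pM) and glucagon (pM) levels
    at which secretion balances degradation for fasting glucose ``G0``,
    and the glucagon-action constant that closes the glucose balance,
    ``a2_eq = (SG + a1*I0) * G0_mgdl / A0``.
    """
    if not (G0_mM > 0):
        raise InvalidArgumentError("G0 must be strictly positive")
    psi0 = hill_response(G0_mM, params.h_rising, params.K, params.psi_scale)
    I0 = params.gamma1 * psi0 / params.n1
    A0 = params.gamma2 * math.exp(-params.k1 * G0_mM) / params.n2
    if A0 <= 0:
        raise DegenerateEquilibriumError("fasting glucagon level is zero")
    a2_eq = (params.SG + params.a1 * I0) * mM_to_mgdl(G0_mM) / A0
    return float(I0), float(A0), float(a2_eq)
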