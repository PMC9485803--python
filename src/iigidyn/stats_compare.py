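"""Model comparison and group statistics.

AICc model selection, exact small-sample Mann-Whitney U and Spearman
rank tests, and group summary tables (mean, SEM, range) over per-subject
parameter sets — the machinery behind the printed cohort tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import InvalidArgumentError

#: Enumeration is exact up to this many distinct group labelings;
#: beyond it the tie-corrected normal approximation is used.
MAX_EXACT_LABELINGS = 125_000


def aicc(rss: float, n: int, p: int) -> float:
    """Akaike information criterion with small-sample correction.

    ``AICc = n ln(RSS/n) + 2p + 2p(p+1)/(n-p-1)`` — the Gaussian
    RSS-profile log-likelihood up to an additive constant that is
    identical across models compared on the same data, so only
    differences are meaningful.
    """
    if n <= p + 1:
        raise InvalidArgumentError("AICc undefined for n <= p + 1")
    if not rss > 0:
        raise InvalidArgumentError("rss must be positive")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


@dataclass(frozen=True)
class ModelComparison:
    delta_aicc: float          # AICc(model 1) - AICc(model 2)
    preferred: str             # "model1" | "model2" | "indistinguishable"
    indistinguishable: bool


def compare_models(fit1, fit2, threshold: float = 2.0) -> ModelComparison:
    """Signed AICc difference between two fits of the same data.

    ``delta = AICc_1 - AICc_2``; positive favors model 2.  Differences
    below ``threshold`` are flagged indistinguishable.
    """
    if fit1.data_hash != fit2.data_hash:
        raise InvalidArgumentError("fits are not on identical data")
    if fit1.weighting != fit2.weighting:
        raise InvalidArgumentError("fits use different weighting modes")
    delta = fit1.aicc - fit2.aicc
    indist = abs(delta) < threshold
    if indist:
        preferred = "indistinguishable"
    else:
        preferred = "model2" if delta > 0 else "model1"
    return ModelComparison(delta_aicc=delta, preferred=preferred,
                           indistinguishable=indist)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Number of (x_i, y_j) pairs with x_i > y_j, plus 1/2 per tie."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(x, y):
    """Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where ``U`` counts pairs with ``x > y`` (half per
    tie).  For small samples the two-sided p is exact by full enumeration
    of group labelings, ``p = 2 min(P(U<=u), P(U>=u))`` capped at 1;
    for larger samples a tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("both samples must be nonempty")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    if math.comb(n + m, min(n, m)) <= MAX_EXACT_LABELINGS:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)  # midranks; rank-sum U handles ties
        total = 0
        le = 0
        ge = 0
        offset = n * (n + 1) / 2.0
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - offset
            total += 1
            if u <= u_obs + 1e-9:
                le += 1
            if u >= u_obs - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le / total, ge / total))
        return u_obs, p
    # normal approximation with tie correction and continuity correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    N = n + m
    tie_term = ((counts ** 3 - counts).sum()) / (N * (N - 1))
    mu = n * m / 2.0
    sigma2 = n * m / 12.0 * (N + 1 - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / math.sqrt(sigma2)
    return u_obs, min(1.0, 2.0 * sps.norm.sf(abs(z)))


def spearman_rank(x, y):
    """Spearman rank correlation ``(rho, p)``.

    rho is the Pearson correlation of midranks.  The two-sided p-value is
    exact (permutation enumeration) for n <= 8, otherwise the usual
    t-approximation with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need equal-length samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidArgumentError("correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    return rho, min(1.0, 2.0 * sps.t.sf(abs(t), n - 2))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def round_sig(x, sig: int = 2):
    """Round to ``sig`` significant figures (display convention of the
    cohort tables).  Zeros and NaNs pass through unchanged."""
    x = np.asarray(x, dtype=float)
    safe = np.where((x == 0) | ~np.isfinite(x), 1.0, np.abs(x))
    mag = 10.0 ** (np.floor(np.log10(safe)) - (sig - 1))
    out = np.where((x == 0) | ~np.isfinite(x), x, np.round(x / mag) * mag)
    return out if out.ndim else float(out)


@dataclass
class SummaryTable:
    """Per parameter x group: mean, SEM and range, with group sizes."""

    table: pd.DataFrame   # index: parameter; columns: (group, stat)
    group_sizes: dict

    def cell(self, parameter: str, group: str, stat: str) -> float:
        return float(self.table.loc[parameter, (group, stat)])

    def rounded(self, sig: int = 2) -> pd.DataFrame:
        return self.table.apply(lambda col: round_sig(col.to_numpy(), sig))


def summarize_parameters(values: pd.DataFrame,
                         group_col: str = "group",
                         parameters: Optional[Sequence[str]] = None
                         ) -> SummaryTable:
    """Group summary (mean, SEM, min, max) of per-subject parameters.

    ``values`` is tidy: one row per subject, a ``group`` column plus one
    column per parameter.  Absent manual delays must already be recorded
    as 0 (the convention of the printed cohort ranges).  SEM uses the
    (n-1)-denominator sample SD.  Raw values are retained; rounding to
    2 significant figures is a display operation (:meth:`SummaryTable.rounded`).
    """
    if parameters is None:
        parameters = [c for c in values.columns
                      if c != group_col and np.issubdtype(values[c].dtype, np.number)]
    groups = list(dict.fromkeys(values[group_col]))
    sizes = {}
    cols = {}
    for g in groups:
        sub = values[values[group_col] == g]
        if len(sub) < 2:
            raise InvalidArgumentError(f"group {g!r} has fewer than 2 subjects")
        sizes[g] = len(sub)
        for stat, fn in (("mean", np.mean),
                         ("sem", lambda a: np.std(a, ddof=1) / math.sqrt(len(a))),
                         ("min", np.min), ("max", np.max)):
            cols[(g, stat)] = [fn(sub[p].to_numpy(dtype=float)) for p in parameters]
    table = pd.DataFrame(cols, index=list(parameters))
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["group", "stat"])
    return SummaryTable(table=table, group_sizes=sizes)


# ---------------------------------------------------------------------------
# shipped per-subject parameter fixtures
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "cs_model1": "table_cs_model1.csv",
    "t2d_model1": "table_t2d_model1.csv",
    "cs_model2": "table_cs_model2.csv",
    "t2d_model2": "table_t2d_model2.csv",
}


def load_table_fixture(name: str) -> pd.DataFrame:
    """Load a shipped per-subject fitted-parameter table.

    Names: ``cs_model1``, ``t2d_model1``, ``cs_model2``, ``t2d_model2``.
    Dash cells of the originals (no delay observed) are encoded as 0.
    """
    try:
        fname = FIXTURE_FILES[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown fixture {name!r}; choose from {sorted(FIXTURE_FILES)}")
    with resources.files("iigidyn.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, comment="#")


def cohort_parameter_frame(model: str = "model1") -> pd.DataFrame:
    """Tidy frame of the shipped fitted parameters for both groups."""
    suffix = "model1" if model == "model1" else "model2"
    frames = []
    for group, key in (("CS", f"cs_{suffix}"), ("T2D", f"t2d_{suffix}")):
        df = load_table_fixture(key).copy()
        df["group"] = group
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
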