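"""Spearman rank correlation of diversity measures against environment.

At the sample sizes of a typical soil survey (here n = 5) the usual
large-sample p-value approximations for Spearman's rho are unreliable, so the
two-sided p-value is computed exactly by enumerating all n! rank permutations
whenever n ≤ 8, falling back to the t-approximation for larger n. A perfect
monotone correlation at n = 5 therefore has p = 2/120 ≈ 0.017, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .alpha import AlphaSummary
from .io import EnvTable

__all__ = ["CorrelationResult", "spearman", "correlate_all"]

_EXACT_MAX_N = 8
_EPS = 1e-12


@dataclass(frozen=True)
class CorrelationResult:
    """One rank-correlation test between a measure and an env variable."""

    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"

    def __str__(self):
        return (f"Spearman({self.x_name}, {self.y_name}): "
                f"rho={self.rho:+.3f}, p={self.p_value:.4g} "
                f"(n={self.n}, {self.method})")


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of mid-rank vectors."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("constant vector: Spearman's rho is undefined")
    return float((rx @ ry) / denom)


def spearman(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman's rho with an exact permutation p-value at small n.

    rho is the Pearson correlation of mid-ranks (ties share average ranks).
    The two-sided p-value is the fraction of the n! permutations of y's ranks
    whose |rho| is at least the observed |rho| (exact for n ≤ 8); for larger n
    the standard t-approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_rho(rx, ry)

    if n <= _EXACT_MAX_N:
        hits = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= abs(rho) - _EPS:
                hits += 1
        return CorrelationResult(x_name, y_name, rho, hits / total, n,
                                 "exact-permutation")
    # t-approximation: t = rho sqrt((n-2)/(1-rho^2))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * sqrt((n - 2) / (1 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(x_name, y_name, rho, min(p, 1.0) or np.nextafter(0, 1),
                             n, "t-approximation")


def correlate_all(alpha: AlphaSummary | pd.DataFrame, env: EnvTable,
                  holm: bool = False) -> pd.DataFrame:
    """Test every (diversity measure, environment variable) pair.

    Sample sets must match exactly; CI bound columns (``*_lo``/``*_hi``) are
    not treated as measures. No multiplicity correction is applied by default,
    but the number of tests performed is recorded in ``DataFrame.attrs`` and a
    Holm-adjusted column is available behind ``holm=True``.
    """
    data = alpha.data if isinstance(alpha, AlphaSummary) else pd.DataFrame(alpha)
    mine, theirs = set(data.index), set(env.sample_ids)
    if mine != theirs:
        raise ValueError(
            f"sample mismatch: only in diversity table {sorted(mine - theirs)}, "
            f"only in env table {sorted(theirs - mine)}")
    envdata = env.data.loc[list(data.index)]
    measures = [c for c in data.columns
                if not (c.endswith("_lo") or c.endswith("_hi"))]
    variables = [c for c in envdata.columns
                 if pd.api.types.is_numeric_dtype(envdata[c])]
    rows = []
    for var in variables:
        for meas in measures:
            r = spearman(envdata[var].to_numpy(), data[meas].to_numpy(),
                         x_name=var, y_name=meas)
            rows.append({"variable": var, "measure": meas, "rho": r.rho,
                         "p_value": r.p_value, "n": r.n, "method": r.method})
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = len(out)
    if holm and len(out):
        order = np.argsort(out["p_value"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_value"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    return out
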