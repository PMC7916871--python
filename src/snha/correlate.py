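"""Correlation matrices with significance levels.

The chain-detection algorithm ranks absolute correlation coefficients, so
this module produces the full symmetric matrix ``r`` together with a
matrix of two-sided p-values derived from the t statistic

    t = r * sqrt((n - 2) / (1 - r^2)),   df = n - 2.

The same t approximation is used for Spearman coefficients (computed on
mid-ranks), which is standard practice at moderate sample sizes and keeps
the operation deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataMatrix

__all__ = ["CorrMatrix", "p_from_r", "correlation_matrix", "significant_mask"]


def p_from_r(r, n: int):
    """Two-sided p-value(s) for correlation coefficient(s) at sample size n."""
    r = np.asarray(r, dtype=float)
    df = n - 2
    if df < 2:
        raise ValueError("p-values need n >= 4")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class CorrMatrix:
    """Symmetric correlation matrix with companion p-values.

    ``r`` keeps the signed coefficients (signs decorate graph edges); the
    chain algorithm ranks their absolute values.  ``n`` is the sample size
    the coefficients were computed from and drives every significance and
    likelihood computation downstream.
    """

    r: np.ndarray
    p: np.ndarray
    n: int
    method: str
    var_names: tuple[str, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "var_names", tuple(str(v) for v in self.var_names))
        k = len(self.var_names)
        if r.shape != (k, k) or p.shape != (k, k):
            raise ValueError("matrix shapes do not match variable names")
        if len(set(self.var_names)) != k:
            raise ValueError("duplicate variable names")
        if not np.array_equal(r, r.T) or not np.array_equal(p, p.T):
            raise ValueError("r and p must be exactly symmetric")
        if np.max(np.abs(r)) > 1.0:
            raise ValueError("|r| must not exceed 1")
        if np.any(np.diag(r) != 1.0):
            raise ValueError("diagonal of r must be 1")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError("p-values must lie in [0, 1]")

    @classmethod
    def from_r(cls, r, n: int, var_names, method: str = "pearson") -> "CorrMatrix":
        """Build a CorrMatrix from coefficients alone; p-values from r and n."""
        r = np.asarray(r, dtype=float)
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        p = p_from_r(r, n)
        p = (p + p.T) / 2.0
        np.fill_diagonal(p, 0.0)
        return cls(r=r, p=p, n=int(n), method=method, var_names=tuple(var_names))

    @property
    def n_var(self) -> int:
        return len(self.var_names)

    @property
    def rho(self) -> np.ndarray:
        """Absolute coefficients, the quantity the chain algorithm ranks."""
        return np.abs(self.r)

    def index(self, name: str) -> int:
        return self.var_names.index(name)

    def submatrix(self, names) -> np.ndarray:
        idx = [self.index(v) for v in names]
        return self.r[np.ix_(idx, idx)]


def correlation_matrix(d: DataMatrix, method: str = "spearman") -> CorrMatrix:
    """Correlation matrix of a data table by Pearson or Spearman (default).

    Requires at least 4 observations (the p-value t statistic has n-2
    degrees of freedom) and no constant column.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown correlation method: {method!r}")
    if d.n_obs < 4:
        raise ValueError(f"need at least 4 observations, got {d.n_obs}")
    sds = d.values.std(axis=0)
    if np.any(sds == 0.0):
        bad = [v for v, s in zip(d.var_names, sds) if s == 0.0]
        raise ValueError(f"zero-variance column(s): {', '.join(bad)}")
    r = d.to_frame().corr(method=method).to_numpy()
    return CorrMatrix.from_r(r, n=d.n_obs, var_names=d.var_names, method=method)


def significant_mask(c: CorrMatrix, alpha: float) -> np.ndarray:
    """Boolean matrix, True where p <= alpha off the diagonal."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    mask = (c.p <= alpha) & ~np.eye(c.n_var, dtype=bool)
    return mask
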