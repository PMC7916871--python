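"""Likelihood-ratio validation of association chains.

A chain of k variables asserts a first-order Markov (chain) dependence:
each member is conditionally normal given only its predecessor, so all
non-adjacent partial correlations vanish.  The unrestricted alternative
is the saturated multivariate normal with free correlation among the k
members, whose MLE is the sample correlation matrix R.

The chain model is decomposable (cliques = adjacent pairs, separators =
interior singletons), so its restricted MLE has closed form and the
deviance reduces to

    chi2 = n * ( sum_adjacent log(1 - r_ab^2) - log det R ),

with degrees of freedom equal to the number of zeroed dependencies,

    df = C(k, 2) - (k - 1) = (k - 1)(k - 2) / 2.

Natural logarithms and the MLE multiplier n (not n-1) are used
throughout; likelihoods are evaluated on the correlation scale, where
means and variances cancel in the ratio.  The p-value is the right-tail
chi-square probability; small p means the chain fails to capture the
dependencies among its members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import CorrMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .chains import Chain

__all__ = [
    "LRTestResult",
    "chain_df",
    "chi2_right_tail",
    "chain_lr_test",
    "count_candidate_chains",
    "lr_table",
]


def chain_df(k: int) -> int:
    """Degrees of freedom of the chain LR test for k members.

    Pairwise dependencies among the members, C(k, 2), minus the k-1
    adjacent-pair parameters the chain retains: (k-1)(k-2)/2.
    """
    if k < 3:
        raise ValueError("chain LR test needs at least 3 members")
    return (k - 1) * (k - 2) // 2


def chi2_right_tail(chi2: float, df: int) -> float:
    """Right-tail chi-square probability (survival function)."""
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    if df < 1:
        raise ValueError("df must be a positive integer")
    return float(stats.chi2.sf(chi2, df))


def count_candidate_chains(I: int, k: int) -> int:
    """Number of reversal-distinct candidate chains of k serial
    correlation coefficients (k+1 ordered variables) among I variables.

    For k = 1 this is simply the C(I, 2) coefficients themselves; for
    k >= 2 ordered selections of k+1 variables are counted with each
    sequence identified with its reversal: I! / (I-k-1)! / 2.
    """
    if I < 2:
        raise ValueError("need at least 2 variables")
    if not 1 <= k <= I - 1:
        raise ValueError(f"k must lie in [1, {I - 1}] for I = {I}")
    if k == 1:
        return math.comb(I, 2)
    return math.perm(I, k + 1) // 2


@dataclass(frozen=True)
class LRTestResult:
    """Per-chain restricted vs. unrestricted Gaussian likelihood ratio."""

    chain: "Chain"
    loglik_unrestricted: float
    loglik_restricted: float
    chi2: float
    df: int
    p_value: float


def _members(chain) -> tuple[str, ...]:
    return tuple(chain.members) if hasattr(chain, "members") else tuple(chain)


def chain_lr_test(chain, c: CorrMatrix) -> LRTestResult:
    """Likelihood-ratio test of a chain's Markov factorization.

    ``chain`` may be a :class:`~snha.chains.Chain` or a plain sequence of
    member names.  Requires the members' sample correlation submatrix to
    be nonsingular and n > k.
    """
    members = _members(chain)
    k = len(members)
    df = chain_df(k)
    n = c.n
    if n <= k:
        raise ValueError(f"sample size n = {n} too small for a {k}-member chain")
    idx = [c.index(v) for v in members]
    R = c.r[np.ix_(idx, idx)]
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < math.log(1e-12):
        raise np.linalg.LinAlgError("singular correlation submatrix for chain "
                                    + "-".join(members))
    adj_r = np.array([c.r[i, j] for i, j in zip(idx[:-1], idx[1:])])
    if np.any(np.abs(adj_r) >= 1.0 - 1e-12):
        raise np.linalg.LinAlgError("degenerate chain: |r| = 1 on an adjacent pair")
    logdet_restricted = float(np.sum(np.log1p(-adj_r**2)))
    chi2 = n * (logdet_restricted - logdet)
    if chi2 < -1e-6:
        raise AssertionError(f"negative deviance {chi2}; numerical failure")
    chi2 = max(chi2, 0.0)
    # full Gaussian log-likelihoods at the respective MLEs (trace term = k)
    const = k * math.log(2.0 * math.pi) + k
    ll_unres = -0.5 * n * (const + logdet)
    ll_res = -0.5 * n * (const + logdet_restricted)
    return LRTestResult(
        chain=chain,
        loglik_unrestricted=ll_unres,
        loglik_restricted=ll_res,
        chi2=float(chi2),
        df=df,
        p_value=chi2_right_tail(chi2, df),
    )


def lr_table(results: Sequence[LRTestResult]) -> pd.DataFrame:
    """Tabulate LR results: chain id, members, df, chi2, p-value."""
    rows = []
    for i, res in enumerate(results, start=1):
        members = _members(res.chain)
        rows.append(
            {
                "chain": i,
                "members": "-".join(members),
                "df": res.df,
                "chi2": res.chi2,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows, columns=["chain", "members", "df", "chi2", "p_value"])
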