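"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid calling the code paths they verify: the chain
enumerator scans every ordered variable sequence and checks the
descending-|r| walk property directly, and the likelihood oracle
maximizes the restricted Gaussian log-likelihood numerically instead of
using the closed-form deviance.
"""

from itertools import permutations

import numpy as np
from scipy import optimize


def enumerate_chains(c, alpha=0.05, abs_threshold=0.1):
    """All reversal-distinct maximal chains (length >= 3), by enumeration.

    A sequence qualifies iff, read from either end, each step goes to the
    unvisited variable with the largest |r| to the current one (ties to
    the earlier variable name), each step clears the |r| threshold and
    significance level, and the sequence cannot be extended at either end.
    """
    I = c.n_var
    rho, p = np.abs(c.r), c.p

    def admissible(i, j):
        return rho[i, j] >= abs_threshold and p[i, j] <= alpha

    def step_ok(seq):
        for t in range(len(seq) - 1):
            prefix = set(seq[: t + 1])
            cur = seq[t]
            cands = [j for j in range(I) if j not in prefix]
            best = max(cands, key=lambda j: (rho[cur, j], -j))
            if best != seq[t + 1] or not admissible(cur, best):
                return False
        return True

    def maximal(seq):
        cands = [j for j in range(I) if j not in set(seq)]
        if not cands:
            return True
        cur = seq[-1]
        best = max(cands, key=lambda j: (rho[cur, j], -j))
        return not admissible(cur, best)

    found = set()
    for k in range(3, I + 1):
        for seq in permutations(range(I), k):
            rev = seq[::-1]
            if step_ok(seq) and maximal(seq) and step_ok(rev) and maximal(rev):
                names = tuple(c.var_names[i] for i in seq)
                if names[-1] < names[0]:
                    names = names[::-1]
                found.add(names)
    return found


def numeric_restricted_chi2(R, n):
    """Deviance of the first-order Markov chain model by direct numeric
    maximization of the restricted Gaussian likelihood.

    Parameters: k-1 adjacent correlations (tanh-transformed) and k log
    variances.  The implied covariance of the chain model has
    corr(i, j) = product of the adjacent correlations between i and j.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]

    def build_sigma(params):
        a = np.tanh(params[: k - 1])
        sd = np.exp(params[k - 1 :] / 2.0)
        M = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                M[i, j] = M[j, i] = np.prod(a[i:j])
        return M * np.outer(sd, sd)

    def negll(params):
        sigma = build_sigma(params)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return 0.5 * n * (logdet + np.trace(np.linalg.solve(sigma, R)))

    adj = np.array([R[i, i + 1] for i in range(k - 1)])
    x0 = np.concatenate([np.arctanh(np.clip(adj, -0.99, 0.99)), np.zeros(k)])
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000, "maxfev": 20000})
    sign, logdet_R = np.linalg.slogdet(R)
    ll_unres = -0.5 * n * (logdet_R + k)
    return 2.0 * (ll_unres + res.fun)
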