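"""Raftery–Lewis run-length convergence diagnostic for MCMC chains.

The chain is dichotomized at its q-quantile and the resulting binary
process is thinned until a first-order Markov chain describes it better
than a second-order one (BIC). The two-state transition probabilities then
give the burn-in (M) and run length (N) needed to estimate the q-quantile
to within ±r with probability s, and the dependence factor I = (M + N)/Nmin
— the inflation over the i.i.d. requirement Nmin (≈ 1 for white-noise
chains, large for sticky ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log

import numpy as np
from scipy.stats import norm


@dataclass
class RafteryLewisResult:
    burn_in: int  # M: iterations to discard
    n_required: int  # N: post-burn-in iterations needed
    n_min: int  # i.i.d. requirement
    dependence_factor: float  # I = (M + N) / n_min
    thin: int  # sub-sampling interval at which the chain is ~first-order
    q: float
    r: float
    s: float


def _markov_order_bic(u: np.ndarray) -> float:
    """BIC for second-order vs first-order Markov fit of binary series u;
    negative values favour first order."""
    n = len(u) - 2
    counts = np.zeros((2, 2, 2))
    for i, j, k in zip(u[:-2], u[1:-1], u[2:]):
        counts[i, j, k] += 1
    g2 = 0.0
    n_j = counts.sum(axis=(0, 2))
    for i in range(2):
        for j in range(2):
            for k in range(2):
                if counts[i, j, k] > 0:
                    fitted = counts[i, j, :].sum() * counts[:, j, k].sum() / n_j[j]
                    g2 += 2.0 * counts[i, j, k] * log(counts[i, j, k] / fitted)
    return g2 - 2.0 * log(n)


def raftery_lewis(chain, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95, eps: float = 0.001) -> RafteryLewisResult:
    """Run-length diagnostic for estimating the q-quantile of a chain.

    Raises if the chain is shorter than the i.i.d. minimum or degenerate
    (constant, so the dichotomization carries no information).
    """
    chain = np.asarray(chain, dtype=float)
    z = norm.ppf(0.5 * (1.0 + s))
    n_min = int(ceil(q * (1.0 - q) * (z / r) ** 2))
    if len(chain) < n_min:
        raise ValueError(
            f"chain of length {len(chain)} is too short; the diagnostic "
            f"needs at least {n_min} iterations for (q={q}, r={r}, s={s})")
    if np.ptp(chain) == 0:
        raise ValueError("constant chain: dichotomization is degenerate")
    cutoff = np.quantile(chain, q)
    u = (chain <= cutoff).astype(np.int64)
    if u.min() == u.max():
        raise ValueError("dichotomized chain is constant; quantile degenerate")

    kthin = 1
    while True:
        ut = u[::kthin]
        if len(ut) < 3 or ut.min() == ut.max():
            break  # over-thinned; keep previous interval
        if _markov_order_bic(ut) < 0:
            break
        kthin += 1
    ut = u[::kthin]

    trans = np.zeros((2, 2))
    for i, j in zip(ut[:-1], ut[1:]):
        trans[i, j] += 1
    row = trans.sum(axis=1)
    alpha = trans[0, 1] / row[0] if row[0] else 0.0  # P(0 -> 1)
    beta = trans[1, 0] / row[1] if row[1] else 0.0  # P(1 -> 0)
    ab = alpha + beta
    if ab <= 0:
        raise ValueError("no state transitions after thinning; chain too sticky")
    lam = abs(1.0 - ab)
    if lam <= 0 or lam >= 1:
        m_star = 1.0  # immediate forgetting (i.i.d.-like chain)
    else:
        m_star = max(log(eps * ab / max(alpha, beta)) / log(lam), 1.0)
    burn = int(ceil(m_star)) * kthin
    n_star = (2.0 - ab) * alpha * beta * (z / r) ** 2 / ab**3
    n_req = int(ceil(n_star)) * kthin
    return RafteryLewisResult(burn, n_req, n_min,
                              (burn + n_req) / n_min, kthin, q, r, s)
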