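"""Bayes B and Bayes Cπ marker-effect samplers.

Both are single-site Gibbs samplers for

    y_d = μ + Z a + H d + ε,   ε ~ N(0, I σ²_e),

with a point mass at zero on each marker effect: effect class c (additive,
dominance) has mixture probability π_c of exclusion. Bayes B gives every
marker its own scaled-inverse-χ² effect variance and keeps π fixed; Bayes Cπ
shares one effect variance per class and samples π from its Beta posterior
(uniform prior), so its posterior mean π̂ can seed Bayes B runs.

Genomic variances are reported on the genetic-value scale: at each stored
iteration the variance over clones of Za, Hd and Za + Hd is recorded, and
posterior means of those series are returned as σ̂²_a, σ̂²_d, σ̂²_g. The
per-iteration residual variance chain is kept in full as the
convergence-monitored series.

The marker sweep is compiled with numba; chains are reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .genotypes import MarkerDesigns


class McmcError(RuntimeError):
    pass


@dataclass
class McmcConfig:
    """Sampler settings: chain length, mixture probabilities and priors.

    ``pi`` / ``pi_dom`` are the prior probabilities that an additive /
    dominance marker effect is exactly zero (Bayes B; ignored by Bayes Cπ,
    which samples them). Effect and residual variance priors are
    scaled-inverse-χ²; scales are solved at run time so the prior mean
    matches a genomic R² of ``r2`` split equally across effect classes.
    """

    n_iter: int = 20000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0
    pi: float = 0.95
    pi_dom: float | None = None
    df_effect: float = 5.0
    df_resid: float = 5.0
    r2: float = 0.5

    def __post_init__(self):
        if not (0 <= self.pi < 1):
            raise ValueError("pi must lie in [0, 1)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    mu: float
    effects_a: np.ndarray
    effects_d: np.ndarray
    inclusion_a: np.ndarray
    inclusion_d: np.ndarray
    sigma2_a: float
    sigma2_d: float
    sigma2_g: float
    sigma2_e: float
    pi_a: float  # posterior mean exclusion probability (Cpi) or the fixed prior
    pi_d: float
    chains: pd.DataFrame  # thinned post-burn-in series of the summary stats
    resid_chain: np.ndarray  # full-length residual-variance series
    n_samples: int
    with_dominance: bool

    def predict(self, Z: np.ndarray, H: np.ndarray | None = None) -> dict:
        """GEBV / GEGV for clones coded on the same marker columns."""
        gebv = Z @ self.effects_a
        gegv = gebv.copy()
        if self.with_dominance:
            if H is None:
                raise ValueError("dominance model needs the H design to predict")
            gegv = gebv + H @ self.effects_d
        return {"gebv": gebv, "gegv": gegv, "yhat": self.mu + gegv}


@njit(cache=True)
def _sweep(e, X, eff, s2j, zz, pi, sigma2_e, common_var, s2_common,
           nu, S):  # pragma: no cover - exercised through the chain
    """One Gibbs sweep over the markers of a single effect class.

    Returns (number included, sum of squared included effects, updated
    common variance placeholder).
    """
    n, m = X.shape
    m_in = 0
    ssq = 0.0
    for j in range(m):
        old = eff[j]
        rhs = zz[j] * old
        for i in range(n):
            rhs += X[i, j] * e[i]
        s2 = s2_common if common_var else s2j[j]
        v1 = zz[j] * s2 + sigma2_e
        logbf = 0.5 * (rhs * rhs * s2 / (sigma2_e * v1)) - 0.5 * np.log(v1 / sigma2_e)
        if pi <= 0.0:
            pin = 1.0
        else:
            if logbf > 500.0:
                logbf = 500.0
            odds = ((1.0 - pi) / pi) * np.exp(logbf)
            pin = odds / (1.0 + odds)
        if np.random.random() < pin:
            lam = sigma2_e / s2
            mean = rhs / (zz[j] + lam)
            new = mean + np.random.standard_normal() * np.sqrt(sigma2_e / (zz[j] + lam))
            m_in += 1
            ssq += new * new
        else:
            new = 0.0
        if new != old:
            diff = new - old
            for i in range(n):
                e[i] -= X[i, j] * diff
            eff[j] = new
        if not common_var:
            if new != 0.0:
                s2j[j] = (nu * S + new * new) / np.random.chisquare(nu + 1.0)
            else:
                s2j[j] = nu * S / np.random.chisquare(nu)
    return m_in, ssq


@njit(cache=True)
def _chain(y, Z, H, use_dom, n_iter, burn, thin, pi_a0, pi_d0, estimate_pi,
           common_var, nu_a, S_a, nu_d, S_d, nu_e, S_e, seed):
    np.random.seed(seed)
    n = y.shape[0]
    m = Z.shape[1]
    zz = np.empty(m)
    hh = np.empty(m)
    for j in range(m):
        sz = 0.0
        sh = 0.0
        for i in range(n):
            sz += Z[i, j] * Z[i, j]
            sh += H[i, j] * H[i, j]
        zz[j] = sz
        hh[j] = sh

    a = np.zeros(m)
    d = np.zeros(m)
    s2aj = np.full(m, S_a)
    s2dj = np.full(m, S_d)
    s2a_common = S_a
    s2d_common = S_d
    mu = y.mean()
    e = y - mu
    sigma2_e = max(np.var(y) / 2.0, 1e-10)
    pi_a = pi_a0
    pi_d = pi_d0

    n_keep = 0
    for it in range(n_iter):
        if it >= burn and (it - burn) % thin == 0:
            n_keep += 1
    stats = np.zeros((n_keep, 8))
    resid_chain = np.zeros(n_iter)
    a_sum = np.zeros(m)
    d_sum = np.zeros(m)
    inc_a = np.zeros(m)
    inc_d = np.zeros(m)
    ok = True

    k = 0
    for it in range(n_iter):
        # intercept
        r0 = mu + e.mean()
        mu_new = r0 + np.random.standard_normal() * np.sqrt(sigma2_e / n)
        for i in range(n):
            e[i] += mu - mu_new
        mu = mu_new

        # with pi estimated, the prior scale tracks the current pi so the
        # implied prior genetic variance stays constant: a sparser model
        # forces larger per-marker variances, keeping inclusion costly and
        # avoiding the degenerate ridge sigma2 -> 0 where the data carry no
        # information about pi
        Sa_t = S_a / max(1.0 - pi_a, 1.0 / m) if estimate_pi else S_a
        m_in_a, ssq_a = _sweep(e, Z, a, s2aj, zz, pi_a, sigma2_e,
                               common_var, s2a_common, nu_a, Sa_t)
        if common_var:
            s2a_common = (nu_a * Sa_t + ssq_a) / np.random.chisquare(nu_a + m_in_a)
        if estimate_pi:
            pi_a = np.random.beta(m - m_in_a + 1.0, m_in_a + 1.0)
        if use_dom:
            Sd_t = S_d / max(1.0 - pi_d, 1.0 / m) if estimate_pi else S_d
            m_in_d, ssq_d = _sweep(e, H, d, s2dj, hh, pi_d, sigma2_e,
                                   common_var, s2d_common, nu_d, Sd_t)
            if common_var:
                s2d_common = (nu_d * Sd_t + ssq_d) / np.random.chisquare(nu_d + m_in_d)
            if estimate_pi:
                pi_d = np.random.beta(m - m_in_d + 1.0, m_in_d + 1.0)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)
        resid_chain[it] = sigma2_e
        if not np.isfinite(sigma2_e) or sigma2_e > 1e12:
            ok = False
            break

        if it >= burn and (it - burn) % thin == 0:
            # genetic values: ga = Za, gd = Hd reconstructed from e
            va = 0.0
            vd = 0.0
            vg = 0.0
            ma_ = 0.0
            md_ = 0.0
            ga = np.zeros(n)
            gd = np.zeros(n)
            for j in range(m):
                if a[j] != 0.0:
                    for i in range(n):
                        ga[i] += Z[i, j] * a[j]
                if use_dom and d[j] != 0.0:
                    for i in range(n):
                        gd[i] += H[i, j] * d[j]
            ma_ = ga.mean()
            md_ = gd.mean()
            for i in range(n):
                va += (ga[i] - ma_) ** 2
                vd += (gd[i] - md_) ** 2
                vg += (ga[i] + gd[i] - ma_ - md_) ** 2
            denom = n - 1.0
            stats[k, 0] = mu
            stats[k, 1] = sigma2_e
            stats[k, 2] = va / denom
            stats[k, 3] = vd / denom
            stats[k, 4] = vg / denom
            stats[k, 5] = pi_a
            stats[k, 6] = pi_d
            stats[k, 7] = float(m_in_a)
            a_sum += a
            d_sum += d
            for j in range(m):
                if a[j] != 0.0:
                    inc_a[j] += 1.0
                if d[j] != 0.0:
                    inc_d[j] += 1.0
            k += 1

    return stats[:k], resid_chain[:min(it + 1, n_iter)], a_sum, d_sum, \
        inc_a, inc_d, k, ok


def _prior_scales(y, Z, H, use_dom, cfg: McmcConfig, pi_a, pi_d):
    """Solve scaled-inverse-χ² scales so prior means match an R² of cfg.r2
    split equally across the active effect classes."""
    vary = float(np.var(y))
    nu = cfg.df_effect
    n_classes = 2 if use_dom else 1
    r2c = cfg.r2 / n_classes
    sum_vz = float(np.sum(np.var(Z, axis=0)))
    mean_s2a = r2c * vary / max((1.0 - pi_a) * sum_vz, 1e-12)
    S_a = mean_s2a * (nu - 2.0) / nu
    if use_dom:
        sum_vh = float(np.sum(np.var(H, axis=0)))
        mean_s2d = r2c * vary / max((1.0 - pi_d) * sum_vh, 1e-12)
        S_d = mean_s2d * (nu - 2.0) / nu
    else:
        S_d = S_a
    S_e = (1.0 - cfg.r2) * vary * (cfg.df_resid - 2.0) / cfg.df_resid
    return S_a, S_d, max(S_e, 1e-12)


def _run(y_d, designs: MarkerDesigns, cfg: McmcConfig, with_dominance,
         estimate_pi, common_var) -> PosteriorSummary:
    y = np.ascontiguousarray(np.asarray(y_d, dtype=float))
    Z = np.ascontiguousarray(designs.Z_add, dtype=float)
    H = np.ascontiguousarray(designs.H_classical, dtype=float)
    if y.shape[0] != Z.shape[0]:
        raise ValueError("response and designs are not aligned")
    pi_a = 0.5 if estimate_pi else cfg.pi
    pi_d = 0.5 if estimate_pi else (cfg.pi_dom if cfg.pi_dom is not None else cfg.pi)
    # with pi estimated the chain rescales by 1/(1-pi) itself, so the base
    # scale here is computed at full inclusion
    S_a, S_d, S_e = _prior_scales(y, Z, H, with_dominance, cfg,
                                  0.0 if estimate_pi else pi_a,
                                  0.0 if estimate_pi else pi_d)
    stats, resid_chain, a_sum, d_sum, inc_a, inc_d, k, ok = _chain(
        y, Z, H, with_dominance, cfg.n_iter, cfg.burn_in, cfg.thin,
        pi_a, pi_d, estimate_pi, common_var,
        cfg.df_effect, S_a, cfg.df_effect, S_d, cfg.df_resid, S_e,
        cfg.seed)
    if not ok:
        raise McmcError("residual variance diverged; check the response scale "
                        "and priors (last finite values in resid_chain)")
    chains = pd.DataFrame(stats, columns=["mu", "sigma2_e", "sigma2_a",
                                          "sigma2_d", "sigma2_g", "pi_a",
                                          "pi_d", "n_included_a"])
    return PosteriorSummary(
        mu=float(chains["mu"].mean()),
        effects_a=a_sum / k, effects_d=d_sum / k,
        inclusion_a=inc_a / k, inclusion_d=inc_d / k,
        sigma2_a=float(chains["sigma2_a"].mean()),
        sigma2_d=float(chains["sigma2_d"].mean()),
        sigma2_g=float(chains["sigma2_g"].mean()),
        sigma2_e=float(chains["sigma2_e"].mean()),
        pi_a=float(chains["pi_a"].mean()), pi_d=float(chains["pi_d"].mean()),
        chains=chains, resid_chain=resid_chain, n_samples=k,
        with_dominance=with_dominance)


def run_bayesB(y_d, designs: MarkerDesigns, cfg: McmcConfig,
               with_dominance: bool = False) -> PosteriorSummary:
    """Bayes B: per-marker effect variances, fixed exclusion probability π."""
    return _run(y_d, designs, cfg, with_dominance,
                estimate_pi=False, common_var=False)


def run_bayesCpi(y_d, designs: MarkerDesigns, cfg: McmcConfig,
                 with_dominance: bool = False) -> PosteriorSummary:
    """Bayes Cπ: one effect variance per class, π sampled (Beta posterior);
    the returned ``pi_a``/``pi_d`` posterior means can seed Bayes B."""
    return _run(y_d, designs, cfg, with_dominance,
                estimate_pi=True, common_var=True)
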