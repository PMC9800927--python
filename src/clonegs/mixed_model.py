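"""Average-information REML for linear mixed models with correlated random effects.

Fits y = Xβ + Σ_k Z_k u_k + e with u_k ~ N(0, K_k σ²_k) and e ~ N(0, I σ²_e),
where each K_k is a known (relationship) matrix or the identity. All
quantities are computed from the mixed-model equations (MME), so the cost is
set by the number of equations (p + Σ q_k), not the number of records:

    M = W'W/σ²_e + blockdiag(0_p, K_k⁻¹/σ²_k),   W = [X | Z_1 | ... ],

whose inverse C is the prediction-error covariance of (β̂, û). Scores, the
average-information matrix and the REML log-likelihood all come from C, û
and the residuals via the standard identities

    tr(P V̇_k)   = q_k/σ²_k − tr(K_k⁻¹ C_kk)/σ²_k²
    y'P V̇_k P y = û_k' K_k⁻¹ û_k / σ²_k²
    AI_kl       = ½ w_k' P w_l,  w_k = Z_k û_k/σ²_k,  w_e = ê/σ²_e.

Updates are average-information steps with an EM fallback whenever an AI
step would leave the parameter space (guaranteeing progress), and variance
components are clamped at a small positive floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

VAR_FLOOR = 1e-8


class REMLError(RuntimeError):
    """Non-convergence or a singular system; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class RandomTerm:
    """One random effect: ``Z`` (N × q incidence) and covariance ``K`` (q × q,
    None meaning identity)."""

    label: str
    Z: np.ndarray
    K: np.ndarray | None = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        self.q = self.Z.shape[1]
        if self.K is not None:
            self.K = np.asarray(self.K, dtype=float)
            if self.K.shape != (self.q, self.q):
                raise ValueError(f"term {self.label}: K shape mismatch")
            try:
                cf = linalg.cho_factor(self.K, lower=True)
            except linalg.LinAlgError as exc:
                raise ValueError(
                    f"term {self.label}: K is not positive definite; "
                    "condition it first (condition_psd)") from exc
            self.K_inv = linalg.cho_solve(cf, np.eye(self.q))
            self.logdet_K = 2.0 * np.sum(np.log(np.diag(cf[0])))
        else:
            self.K_inv = None
            self.logdet_K = 0.0


@dataclass
class REMLResult:
    variance_components: dict  # label -> sigma^2, plus "residual"
    beta: np.ndarray
    u: dict  # label -> BLUP vector
    pev: dict  # label -> prediction error variance (diag of C block)
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)

    @property
    def sigma2_e(self) -> float:
        return self.variance_components["residual"]


def _loglik(yPy, sigma2s, terms, N, p, logdet_M, sigma2_e):
    ld = N * np.log(sigma2_e)
    for t in terms:
        ld += t.q * np.log(sigma2s[t.label]) + t.logdet_K
    return -0.5 * (yPy + ld + logdet_M + (N - p) * np.log(2.0 * np.pi))


def mme_solve(y, X, terms, sigma2s) -> REMLResult:
    """Solve the mixed-model equations at fixed variance components
    (``sigma2s``: label -> value, plus "residual"); no REML iteration.

    Useful for equivalence checks (G-BLUP vs marker-effect ridge at a
    matched variance ratio) and for prediction at known components.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, p = X.shape
    W = np.hstack([X] + [t.Z for t in terms])
    se = float(sigma2s["residual"])
    M = W.T @ W / se
    slices, off = [], p
    for t in terms:
        sl = slice(off, off + t.q)
        blk = M[sl, sl]
        if t.K_inv is None:
            blk[np.diag_indices_from(blk)] += 1.0 / sigma2s[t.label]
        else:
            blk += t.K_inv / sigma2s[t.label]
        slices.append(sl)
        off += t.q
    cf = linalg.cho_factor(M, lower=True)
    C = linalg.cho_solve(cf, np.eye(off))
    s = C @ (W.T @ y / se)
    u = {t.label: s[sl].copy() for t, sl in zip(terms, slices)}
    pev = {t.label: np.diag(C[sl, sl]).copy() for t, sl in zip(terms, slices)}
    comps = {t.label: float(sigma2s[t.label]) for t in terms}
    comps["residual"] = se
    return REMLResult(comps, s[:p].copy(), u, pev, float("nan"), True, 0, [])


def reml_fit(y, X, terms, init=None, max_iter=200, rtol=1e-6, ltol=1e-8,
             method="ai", n_em_start=2, verbose=False) -> REMLResult:
    """Estimate variance components by REML and solve the MME at convergence.

    Parameters
    ----------
    y : (N,) response
    X : (N, p) fixed-effect design, full column rank
    terms : list of RandomTerm
    init : optional dict label -> starting value (labels + "residual")
    method : "ai" (average information with EM fallback) or "em" (pure EM,
        monotone in the REML log-likelihood)
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N, p = X.shape
    if N < len(terms) + p + 1:
        raise ValueError("too few records for the requested model")
    labels = [t.label for t in terms]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate random-term labels")

    W = np.hstack([X] + [t.Z for t in terms])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    slices, off = [], p
    for t in terms:
        slices.append(slice(off, off + t.q))
        off += t.q
    dim = off

    vary = float(np.var(y)) or 1.0
    ncomp = len(terms) + 1
    if init is None:
        sig = {lab: vary / ncomp for lab in labels}
        sig["residual"] = vary / ncomp
    else:
        sig = {lab: float(init.get(lab, vary / ncomp)) for lab in labels}
        sig["residual"] = float(init.get("residual", vary / ncomp))
    floor = max(VAR_FLOOR, VAR_FLOOR * vary)

    def assemble(sigma):
        se_ = sigma["residual"]
        M = WtW / se_
        for t, sl in zip(terms, slices):
            blk = M[sl, sl]
            if t.K_inv is None:
                blk[np.diag_indices_from(blk)] += 1.0 / sigma[t.label]
            else:
                blk += t.K_inv / sigma[t.label]
        cf = linalg.cho_factor(M, lower=True)
        return cf, 2.0 * np.sum(np.log(np.diag(cf[0])))

    def loglik_at(vec):
        sigma = dict(zip(labels + ["residual"], vec))
        try:
            cf, logdet_M = assemble(sigma)
        except linalg.LinAlgError:
            return -np.inf
        s_ = linalg.cho_solve(cf, Wty / sigma["residual"])
        yPy_ = (yty - s_ @ Wty) / sigma["residual"]
        return _loglik(yPy_, sigma, terms, N, p, logdet_M, sigma["residual"])

    trace = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        se = sig["residual"]
        try:
            cf, logdet_M = assemble(sig)
        except linalg.LinAlgError as exc:
            raise REMLError(
                "singular mixed-model equations (rank-deficient fixed design "
                "or degenerate covariance)", trace) from exc
        C = linalg.cho_solve(cf, np.eye(dim))
        s = C @ (Wty / se)
        yPy = (yty - s @ Wty) / se
        ehat = y - W @ s
        ll = _loglik(yPy, sig, terms, N, p, logdet_M, se)

        # scores and data-parts per component (terms then residual)
        tr_pv = np.empty(ncomp)
        ypvpy = np.empty(ncomp)
        wvecs = []
        for i, (t, sl) in enumerate(zip(terms, slices)):
            Ckk = C[sl, sl]
            uk = s[sl]
            s2 = sig[t.label]
            if t.K_inv is None:
                tr_pv[i] = t.q / s2 - np.trace(Ckk) / s2**2
                ypvpy[i] = (uk @ uk) / s2**2
            else:
                tr_pv[i] = t.q / s2 - np.sum(t.K_inv * Ckk) / s2**2
                ypvpy[i] = (uk @ (t.K_inv @ uk)) / s2**2
            wvecs.append(t.Z @ uk / s2)
        tr_pv[-1] = N / se - np.sum(C * WtW) / se**2
        ypvpy[-1] = (ehat @ ehat) / se**2
        wvecs.append(ehat / se)
        score = -0.5 * (tr_pv - ypvpy)

        theta = np.array([sig[lab] for lab in labels] + [sig["residual"]])
        # components stuck at the zero boundary (score still pushing down)
        # are pinned to the floor and excluded from the update system
        pinned = (theta <= 20.0 * floor) & (score < 0.0)
        pinned[-1] = False  # residual variance never pins
        free = ~pinned
        new = None
        used = "em"
        if method == "ai" and it > n_em_start and free.any():
            Wm = np.column_stack([w for w, f in zip(wvecs, free) if f])
            PW = (Wm - W @ (C @ (W.T @ Wm)) / se) / se
            AI = 0.5 * (Wm.T @ PW)
            AI = (AI + AI.T) / 2.0
            try:
                delta_f = np.linalg.solve(AI, score[free])
            except np.linalg.LinAlgError:
                delta_f = None
            if delta_f is not None and np.all(np.isfinite(delta_f)):
                # projected AI step with backtracking: accept only if the
                # REML log-likelihood does not decrease, halving the step
                # toward the current point otherwise
                for _ in range(8):
                    cand = theta.copy()
                    cand[free] = np.maximum(theta[free] + delta_f, floor)
                    cand[pinned] = floor
                    if loglik_at(cand) >= ll - 1e-10:
                        new = cand
                        used = "ai"
                        break
                    delta_f = delta_f / 2.0
        if new is None:
            # EM update (monotone in the REML log-likelihood)
            qs = np.array([t.q for t in terms] + [N], dtype=float)
            new = np.maximum(theta + theta**2 * (ypvpy - tr_pv) / qs, floor)
            new[pinned] = floor

        rel = np.max(np.abs(new[free] - theta[free]) /
                     np.maximum(np.abs(theta[free]), floor)) if free.any() else 0.0
        trace.append({"iter": it, "loglik": ll, "step": used,
                      **dict(zip(labels + ["residual"], theta))})
        if verbose:
            print(f"  it {it:3d} [{used}] ll={ll:.6f} " +
                  " ".join(f"{l}={v:.4g}" for l, v in zip(labels + ['e'], theta)))
        for lab, v in zip(labels + ["residual"], new):
            sig[lab] = float(v)
        if rel < rtol or (it > n_em_start and abs(ll - prev_ll) < ltol):
            converged = True
            break
        prev_ll = ll

    if not converged:
        raise REMLError(f"REML did not converge in {max_iter} iterations", trace)

    # final solve at converged components
    se = sig["residual"]
    cf, logdet_M = assemble(sig)
    C = linalg.cho_solve(cf, np.eye(dim))
    s = C @ (Wty / se)
    yPy = (yty - s @ Wty) / se
    ll = _loglik(yPy, sig, terms, N, p, logdet_M, se)

    u = {t.label: s[sl].copy() for t, sl in zip(terms, slices)}
    pev = {t.label: np.diag(C[sl, sl]).copy() for t, sl in zip(terms, slices)}
    return REMLResult(dict(sig), s[:p].copy(), u, pev, float(ll),
                      converged, it, trace)
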