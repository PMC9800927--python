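"""G-BLUP and RKHS genomic prediction over deregressed phenotypes.

The model is y_d = Jμ + Σ_k Z u_k + ε with each random term following
u_k ~ N(0, R_k σ²_k) for a relationship matrix R_k: the additive G alone
(G-BLUP A), G plus a dominance matrix D or D* (G-BLUP A+D), or a Gaussian
kernel K (RKHS — one code path, a different covariance). Clones without
phenotypes are carried in the random-effect covariance so their solutions
(GEBV for additive terms, GEGV = summed genetic solutions) fall out of the
same mixed-model-equations solve.

Genomic heritabilities follow the variance-ratio definitions
ĥ² = σ̂²_a/(σ̂²_g + σ̂²_e) and Ĥ² = σ̂²_g/(σ̂²_g + σ̂²_e) with
σ̂²_g the summed genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinship import RelationshipMatrix
from .mixed_model import RandomTerm, REMLResult, reml_fit

GENETIC_LABELS = ("additive", "dominance", "genotypic")


@dataclass
class ModelSpec:
    """Response vector plus the genomic random terms to fit.

    ``y_d`` is aligned to ``clone_ids``; entries may be NaN for genotyped
    but unphenotyped clones (masked records). Every relationship matrix
    must be over exactly ``clone_ids`` in order.
    """

    y_d: np.ndarray
    clone_ids: np.ndarray
    random_terms: list  # [(RelationshipMatrix, label)]

    def __post_init__(self):
        self.y_d = np.asarray(self.y_d, dtype=float)
        self.clone_ids = np.asarray(self.clone_ids)
        n = len(self.clone_ids)
        if self.y_d.shape != (n,):
            raise ValueError("y_d must align with clone_ids")
        for rm, label in self.random_terms:
            if label not in GENETIC_LABELS:
                raise ValueError(f"unknown term label {label!r}")
            if rm.n != n or not np.array_equal(np.asarray(rm.clone_ids),
                                               self.clone_ids):
                raise ValueError(
                    f"relationship matrix for {label!r} does not cover the "
                    "spec's clones in order")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y_d)


@dataclass
class FitResult:
    """Converged variance components and per-clone genetic solutions."""

    variance_components: dict  # label -> sigma^2 (genetic terms)
    sigma2_e: float
    mu: float
    clone_ids: np.ndarray
    solutions: dict  # label -> per-clone effect vector
    loglik: float
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)

    @property
    def sigma2_a(self) -> float:
        return self.variance_components.get("additive", 0.0)

    @property
    def sigma2_d(self) -> float:
        return self.variance_components.get("dominance", 0.0)

    @property
    def sigma2_g(self) -> float:
        return float(sum(self.variance_components.values()))

    @property
    def gebv(self) -> np.ndarray:
        """Breeding values: the additive-term solutions."""
        return self.solutions.get(
            "additive", np.zeros(len(self.clone_ids)))

    @property
    def gegv(self) -> np.ndarray:
        """Genotypic values: sum of all genetic-term solutions."""
        return sum(self.solutions.values())


def fit_gblup(spec: ModelSpec, init=None, max_iter=200, rtol=1e-6,
              method="ai") -> FitResult:
    """REML fit of the genomic model; masked (NaN) records are predicted,
    not fitted."""
    obs = spec.observed
    n = len(spec.clone_ids)
    if obs.sum() < 10:
        raise ValueError("need at least 10 phenotyped clones")
    y = spec.y_d[obs]
    sel = np.eye(n)[obs]  # records -> clones incidence
    terms = [RandomTerm(label, sel, rm.values) for rm, label in spec.random_terms]
    X = np.ones((obs.sum(), 1))
    res = reml_fit(y, X, terms, init=init, max_iter=max_iter, rtol=rtol,
                   method=method)
    vc = {label: res.variance_components[label]
          for _, label in spec.random_terms}
    return FitResult(vc, res.sigma2_e, float(res.beta[0]), spec.clone_ids,
                     {lab: res.u[lab] for lab in vc}, res.loglik,
                     res.converged, res.n_iter, res.trace)


def heritability_ratios(sigma2_a: float, sigma2_g: float,
                        sigma2_e: float) -> tuple:
    """Narrow- and broad-sense genomic heritability from raw components:
    ĥ² = σ²_a/(σ²_g + σ²_e), Ĥ² = σ²_g/(σ²_g + σ²_e)."""
    tot = sigma2_g + sigma2_e
    if tot <= 0:
        raise ValueError("all variance components are zero")
    return sigma2_a / tot, sigma2_g / tot


def heritabilities(fit: FitResult) -> tuple:
    """(ĥ², Ĥ²) from a converged fit."""
    return heritability_ratios(fit.sigma2_a, fit.sigma2_g, fit.sigma2_e)


def predict_new(fit: FitResult, spec: ModelSpec, target_clones) -> dict:
    """GEBV/GEGV for genotyped, unphenotyped clones already carried in the
    relationship matrices (whole-matrix solve): a lookup into the solved
    effects, erroring on clones absent from the kinship."""
    index = {c: i for i, c in enumerate(fit.clone_ids)}
    rows = []
    for c in target_clones:
        if c not in index:
            raise KeyError(f"clone {c!r} absent from the relationship matrices")
        rows.append(index[c])
    rows = np.asarray(rows)
    return {"clone_ids": np.asarray(list(target_clones)),
            "gebv": fit.gebv[rows], "gegv": fit.gegv[rows]}
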