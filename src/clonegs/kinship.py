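"""Genomic relationship matrices: additive G, dominance D and D*, Gaussian K.

All four constructors return a :class:`RelationshipMatrix` — a tagged
symmetric n × n matrix over the same clone ordering — built from the marker
designs of :mod:`clonegs.genotypes`:

* ``G  = Z Zᵀ / 2Σ pᵢ(1-pᵢ)``                 (VanRaden scaling)
* ``D  = H Hᵀ / Σ (2pᵢqᵢ)²``                  (classical / Vitezica)
* ``D* = H* H*ᵀ / Σ 2pᵢqᵢ(1-2pᵢqᵢ)``          (genotypic / Su)
* ``K  = exp(-h · Δ / median(Δ))``            with Δ the squared Euclidean
  distances between clone rows of the {-1,0,1} coding and the median taken
  over off-diagonal entries; ``h`` defaults to 1.

Each scaling makes the expected diagonal ≈ 1 under Hardy–Weinberg
proportions. :func:`condition_psd` bends a numerically indefinite matrix by
diagonal inflation so downstream REML solvers can invert it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .genotypes import GenotypeMatrix, MarkerDesigns

KINDS = ("additive", "dom_classical", "dom_genotypic", "gaussian_kernel")


class KinshipError(ValueError):
    pass


@dataclass
class RelationshipMatrix:
    kind: str
    values: np.ndarray
    clone_ids: np.ndarray
    scaling_constant: float
    bending_applied: bool = False

    def __post_init__(self):
        if self.kind not in KINDS:
            raise KinshipError(f"unknown kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise KinshipError("relationship matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise KinshipError("relationship matrix must be symmetric")
        self.values = (v + v.T) / 2.0  # scrub roundoff asymmetry

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.clone_ids, columns=self.clone_ids)


def _cross(H: np.ndarray, denom: float, kind: str, ids) -> RelationshipMatrix:
    if denom <= 0 or not np.isfinite(denom):
        raise KinshipError(f"{kind}: zero or invalid scaling denominator")
    return RelationshipMatrix(kind, H @ H.T / denom, np.asarray(ids), float(denom))


def additive_G(designs: MarkerDesigns) -> RelationshipMatrix:
    """VanRaden additive matrix G = Z Zᵀ / 2Σ pᵢ(1-pᵢ)."""
    if designs.Z_add.shape[1] < 2:
        raise KinshipError("need at least 2 markers")
    denom = 2.0 * np.sum(designs.p * (1.0 - designs.p))
    return _cross(designs.Z_add, denom, "additive", designs.clone_ids)


def dominance_classical(designs: MarkerDesigns,
                        denominator: float | None = None) -> RelationshipMatrix:
    """Classical dominance matrix D = H Hᵀ / Σ (2pᵢqᵢ)²."""
    pq = designs.p * (1.0 - designs.p)
    denom = float(np.sum((2.0 * pq) ** 2)) if denominator is None else denominator
    return _cross(designs.H_classical, denom, "dom_classical", designs.clone_ids)


def dominance_genotypic(designs: MarkerDesigns,
                        denominator: float | None = None) -> RelationshipMatrix:
    """Genotypic dominance matrix D* = H* H*ᵀ / Σ 2pᵢqᵢ(1-2pᵢqᵢ)."""
    tpq = 2.0 * designs.p * (1.0 - designs.p)
    denom = float(np.sum(tpq * (1.0 - tpq))) if denominator is None else denominator
    return _cross(designs.H_genotypic, denom, "dom_genotypic", designs.clone_ids)


def gaussian_kernel(g: GenotypeMatrix, h: float = 1.0,
                    squared: bool = True) -> RelationshipMatrix:
    """Gaussian kernel K = exp(-h Δ / median(Δ)) over marker distances.

    Δ holds pairwise squared Euclidean distances (plain distances with
    ``squared=False``) between clone rows of the {-1,0,1} additive coding;
    the normalizing median is taken over off-diagonal entries only, so the
    diagonal is exactly 1.
    """
    if h <= 0:
        raise KinshipError("bandwidth h must be positive")
    Z = g.dosages - 1.0
    d = pdist(Z, metric="sqeuclidean" if squared else "euclidean")
    med = float(np.median(d))
    if med <= 0:
        raise KinshipError("all pairwise marker distances are zero")
    K = np.exp(-h * squareform(d) / med)
    np.fill_diagonal(K, 1.0)
    return RelationshipMatrix("gaussian_kernel", K, np.asarray(g.clone_ids), med)


def condition_psd(r: RelationshipMatrix, epsilon: float = 1e-6,
                  tol: float = 1e-8) -> RelationshipMatrix:
    """Bend a numerically indefinite matrix by diagonal inflation.

    If the smallest eigenvalue is below ``tol`` the diagonal is shifted by
    ``max(epsilon, -min_eig + epsilon)`` so the result is safely positive
    definite (invertible by downstream REML solvers); a comfortably PSD
    input is returned unchanged.
    """
    lam = r.min_eigenvalue()
    if lam >= tol:
        return r
    if epsilon <= 0:
        raise KinshipError("matrix is numerically indefinite; "
                           "pass epsilon > 0 to bend it")
    v = r.values.copy()
    shift = max(epsilon, -lam + epsilon)
    v[np.diag_indices_from(v)] += shift
    return RelationshipMatrix(r.kind, v, r.clone_ids, r.scaling_constant,
                              bending_applied=True)
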