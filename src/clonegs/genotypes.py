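"""SNP dosage matrices: loading, quality control, imputation and marker codings.

A :class:`GenotypeMatrix` holds clone × marker dosages (counts of the major
allele, 0/1/2, with ``-1`` as the missing sentinel in the TSV dialect and
``./.`` in VCF) together with per-marker major-allele frequencies ``p``.
From it, :func:`build_designs` derives the three marker codings used by the
downstream predictors:

* additive ``Z``: {-1, 0, +1} for {mm, Mm, MM}, optionally column-centered;
* classical dominance ``H``: {-2q², 2pq, -2p²} — the breeding
  parameterization whose columns have zero mean under Hardy–Weinberg
  proportions, making additive and dominance variance components orthogonal;
* genotypic dominance ``H*``: {-2pq, p²+q², -2pq}.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


class GenotypeError(ValueError):
    """Raised for malformed or out-of-domain genotype input."""


@dataclass
class GenotypeMatrix:
    """Clone × marker dosage matrix with allele frequencies.

    ``dosages`` counts copies of the major allele per clone and marker;
    float dtype so that mean-imputed (fractional) dosages are representable.
    ``p`` is the per-marker major-allele frequency computed from non-missing
    calls only (in [0.5, 1) once major orientation is enforced).
    """

    clone_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray  # n × m, float; MISSING (-1) marks no-calls
    p: np.ndarray  # m major-allele frequencies
    imputed: bool = False

    def __post_init__(self) -> None:
        self.clone_ids = np.asarray(self.clone_ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(set(self.clone_ids.tolist())) != self.n_clones:
            raise GenotypeError("duplicate clone ids")
        if len(set(self.marker_ids.tolist())) != self.n_markers:
            raise GenotypeError("duplicate marker ids")
        if self.dosages.shape != (self.n_clones, self.n_markers):
            raise GenotypeError("dosage matrix shape does not match ids")

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclass
class MarkerDesigns:
    """Additive and dominance design matrices derived from a GenotypeMatrix."""

    Z_add: np.ndarray
    H_classical: np.ndarray
    H_genotypic: np.ndarray
    p: np.ndarray
    clone_ids: np.ndarray
    coding_note: str = ""


def _freq_from_dosages(dosages: np.ndarray) -> np.ndarray:
    """Frequency of the coded allele from non-missing calls only."""
    d = np.ma.masked_equal(dosages, MISSING)
    if (d.count(axis=0) == 0).any():
        raise GenotypeError("marker with no called genotypes")
    return np.asarray(d.mean(axis=0) / 2.0)


def _orient_major(dosages: np.ndarray, freq: np.ndarray):
    """Flip markers so the coded allele is the major one (p >= 0.5)."""
    flip = freq < 0.5
    out = dosages.copy()
    cols = out[:, flip]
    miss = cols == MISSING
    cols = 2.0 - cols
    cols[miss] = MISSING
    out[:, flip] = cols
    p = np.where(flip, 1.0 - freq, freq)
    return out, p


def from_dosages(clone_ids, marker_ids, dosages, orient_major: bool = True) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array, computing frequencies."""
    dosages = np.asarray(dosages, dtype=float)
    valid = (dosages == MISSING) | np.isin(dosages, (0.0, 1.0, 2.0))
    if not valid.all():
        bad = dosages[~valid].ravel()[0]
        raise GenotypeError(f"dosage value {bad!r} outside {{0,1,2}} / missing sentinel")
    freq = _freq_from_dosages(dosages)
    if orient_major:
        dosages, freq = _orient_major(dosages, freq)
    return GenotypeMatrix(np.asarray(clone_ids), np.asarray(marker_ids), dosages, freq)


def load_genotypes(path, missing_policy: str = "keep", orient_major: bool = True) -> GenotypeMatrix:
    """Load a dosage matrix from a TSV or VCF file.

    TSV dialect: header row of marker ids, first column clone id, integer
    dosages 0/1/2, ``-1`` missing. VCF: biallelic SNP records only;
    multi-allelic records are skipped with a logged count.

    missing_policy: "keep" retains the sentinel (call :func:`impute_mean`
    later); "impute" mean-imputes immediately.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        g = _load_vcf(path, orient_major=orient_major)
    else:
        g = _load_tsv(path, orient_major=orient_major)
    if missing_policy == "impute":
        g = impute_mean(g)
    elif missing_policy != "keep":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return g


def _load_tsv(path: str, orient_major: bool = True) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise GenotypeError("duplicate clone ids in TSV")
    if df.columns.duplicated().any():
        raise GenotypeError("duplicate marker ids in TSV")
    return from_dosages(df.index.to_numpy(), df.columns.to_numpy(),
                        df.to_numpy(dtype=float), orient_major=orient_major)


def _load_vcf(path: str, orient_major: bool = True) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = np.asarray(vcf.samples)
    marker_ids, rows = [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(rec.genotypes, dtype=object)
        dos = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            dos[i] = MISSING if (a < 0 or b < 0) else float(a + b)
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        rows.append(dos)
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic VCF records")
    if not rows:
        raise GenotypeError("no biallelic SNP records in VCF")
    return from_dosages(samples, np.asarray(marker_ids), np.array(rows).T,
                        orient_major=orient_major)


def quality_filter(g: GenotypeMatrix, min_call_rate: float = 0.90,
                   min_maf: float = 0.05) -> GenotypeMatrix:
    """Drop markers with call rate below ``min_call_rate`` or MAF not
    strictly above ``min_maf`` (a marker at MAF exactly 0.05 is removed)."""
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    cr_ok = g.call_rate() >= min_call_rate
    maf_ok = g.maf() > min_maf
    keep = cr_ok & maf_ok
    logger.info("quality_filter: removed %d markers (call rate) + %d (MAF) of %d",
                int((~cr_ok).sum()), int((cr_ok & ~maf_ok).sum()), g.n_markers)
    if not keep.any():
        raise GenotypeError("quality_filter removed every marker")
    return GenotypeMatrix(g.clone_ids, g.marker_ids[keep], g.dosages[:, keep],
                          g.p[keep], imputed=g.imputed)


def impute_mean(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace each missing dosage by its marker mean 2p (naive imputation)."""
    miss = g.missing_mask
    if not miss.any():
        return replace(g, imputed=True)
    dos = g.dosages.copy()
    fill = np.broadcast_to(2.0 * g.p, dos.shape)
    dos[miss] = fill[miss]
    return GenotypeMatrix(g.clone_ids, g.marker_ids, dos, g.p, imputed=True)


def _interp_coding(dosages: np.ndarray, at0: np.ndarray, at1: np.ndarray,
                   at2: np.ndarray) -> np.ndarray:
    """Evaluate a per-genotype coding, linearly interpolated for fractional
    (mean-imputed) dosages between the adjacent genotype classes."""
    lo = np.where(dosages <= 1.0, at0, at1)
    hi = np.where(dosages <= 1.0, at1, at2)
    t = np.where(dosages <= 1.0, dosages, dosages - 1.0)
    return lo + t * (hi - lo)


def build_designs(g: GenotypeMatrix, center_additive: bool = True) -> MarkerDesigns:
    """Construct additive and dominance design matrices.

    With dosage d counting major alleles (mm=0, Mm=1, MM=2):

    * Z_add = d - 1 (the {-1,0,1} coding), minus its column mean 2p-1 when
      ``center_additive`` (the default);
    * H_classical: mm → -2p², Mm → 2pq, MM → -2q²;
    * H_genotypic: mm → -2pq, Mm → p²+q², MM → -2pq.
    """
    if g.missing_mask.any():
        raise GenotypeError("designs require imputed (no-missing) genotypes")
    p, q = g.p, g.q
    if ((p <= 0) | (p >= 1)).any():
        raise GenotypeError("monomorphic marker (p in {0,1}); filter first")
    d = g.dosages
    Z = d - 1.0
    note = "Z={-1,0,1}"
    if center_additive:
        Z = Z - (2.0 * p - 1.0)
        note = "Z centered: d-2p"
    ones = np.ones_like(p)
    H_cl = _interp_coding(d, -2.0 * p**2 * ones, 2.0 * p * q, -2.0 * q**2 * ones)
    H_ge = _interp_coding(d, -2.0 * p * q, p**2 + q**2, -2.0 * p * q)
    note += "; H_classical=(-2q^2, 2pq, -2p^2); H_genotypic=(-2pq, p^2+q^2, -2pq)"
    return MarkerDesigns(Z, H_cl, H_ge, p.copy(), g.clone_ids.copy(), note)
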