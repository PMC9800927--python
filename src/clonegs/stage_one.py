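"""Stage-one trial analysis: trait derivation, clone BLUPs and deregression.

Multi-trial plot data (clone × location × year × replicate) are fitted with

    y_ijl = μ + c_i + β_j + r_l(j) + ε_ijl

where c_i is the random clone effect (variance σ²_c), β_j the fixed
location-year combination, r_l(j) the random replicate nested in
location-year, and ε the plot residual. Per-clone BLUPs and their prediction
error variances (PEV) come from the inverse MME coefficient matrix;
deregression divides each BLUP by its reliability r² = 1 − PEV/σ̂²_c so the
stage-two response is free of shrinkage.

Trait derivation follows root-sampling practice: dry matter content from
the specific-gravity weighings DMC(%) = (WA/(WA−WW))·158.3 − 142, and dry
root yield DRY = FRY × DMC/100.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixed_model import RandomTerm, reml_fit

logger = logging.getLogger(__name__)

DMC_PLAUSIBLE = (17.0, 38.0)  # field amplitude; values outside are logged


def dmc_from_weights(wa, ww):
    """Dry matter content (%) from air weight WA (kg) and water weight WW (kg).

    Values outside the plausible field amplitude are returned unclamped but
    logged as suspect.
    """
    wa = np.asarray(wa, dtype=float)
    ww = np.asarray(ww, dtype=float)
    if np.any(wa <= ww) or np.any(ww < 0) or np.any(wa <= 0):
        raise ValueError("require WA > WW >= 0 and WA > 0 (non-physical buoyancy)")
    dmc = (wa / (wa - ww)) * 158.3 - 142.0
    n_suspect = int(np.sum((dmc < DMC_PLAUSIBLE[0]) | (dmc > DMC_PLAUSIBLE[1])))
    if n_suspect:
        logger.warning("dmc_from_weights: %d value(s) outside the plausible "
                       "%s%% amplitude", n_suspect, DMC_PLAUSIBLE)
    return dmc if dmc.ndim else float(dmc)


def dry_from_fry_dmc(fry, dmc):
    """Dry root yield (t/ha) = FRY (t/ha) × DMC(%) / 100."""
    fry = np.asarray(fry, dtype=float)
    dmc = np.asarray(dmc, dtype=float)
    if np.any(fry < 0):
        raise ValueError("FRY must be non-negative")
    out = fry * dmc / 100.0
    return out if out.ndim else float(out)


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Add dmc_pct (from wa_kg/ww_kg) and dry_tha (from fry_tha × dmc)
    columns where the raw measurements are present."""
    out = table.copy()
    if {"wa_kg", "ww_kg"}.issubset(out.columns):
        ok = out["wa_kg"].notna() & out["ww_kg"].notna()
        out.loc[ok, "dmc_pct"] = dmc_from_weights(out.loc[ok, "wa_kg"].to_numpy(),
                                                  out.loc[ok, "ww_kg"].to_numpy())
    if "fry_tha" in out.columns and "dmc_pct" in out.columns:
        ok = out["fry_tha"].notna() & out["dmc_pct"].notna()
        out.loc[ok, "dry_tha"] = dry_from_fry_dmc(out.loc[ok, "fry_tha"].to_numpy(),
                                                  out.loc[ok, "dmc_pct"].to_numpy())
    return out


@dataclass
class Stage1Fit:
    """Variance components, fixed trial effects and per-clone records."""

    sigma2_c: float
    sigma2_r: float
    sigma2_e: float
    mu: float
    fixed_effects: pd.Series  # per location-year
    records: pd.DataFrame  # clone, blup, pev, reliability
    loglik: float
    trait: str = ""

    @property
    def H2_pheno(self) -> float:
        """Plot-level broad-sense heritability σ²_c/(σ²_c + σ²_e)."""
        return self.sigma2_c / (self.sigma2_c + self.sigma2_e)


def fit_stage1(table: pd.DataFrame, trait: str, max_iter=200) -> Stage1Fit:
    """REML fit of the trial mixed model for one trait column.

    ``table`` needs columns clone, location, year, rep and the trait.
    Location-years with fewer than two records are dropped with a warning
    (their fixed effect would be confounded with the plot residual).
    """
    need = {"clone", "location", "year", "rep"}
    if not need.issubset(table.columns):
        raise ValueError(f"trial table must have columns {sorted(need)}")
    if trait not in table.columns:
        raise ValueError(f"trait column {trait!r} absent from trial table")
    df = table.loc[table[trait].notna(),
                   ["clone", "location", "year", "rep", trait]].copy()
    df["loc_year"] = df["location"].astype(str) + ":" + df["year"].astype(str)
    sizes = df.groupby("loc_year")[trait].size()
    tiny = sizes.index[sizes < 2]
    if len(tiny):
        warnings.warn(f"dropping {len(tiny)} location-year(s) with a single "
                      "record (fixed effect confounded with residual)")
        df = df[~df["loc_year"].isin(tiny)]
    if df["loc_year"].nunique() < 2:
        raise ValueError("need at least 2 location-year trials")

    y = df[trait].to_numpy(dtype=float)
    ly = pd.Categorical(df["loc_year"])
    X = np.column_stack([np.ones(len(df))] +
                        [(ly.codes == k).astype(float)
                         for k in range(1, len(ly.categories))])
    clones = pd.Categorical(df["clone"])
    Zc = np.zeros((len(df), len(clones.categories)))
    Zc[np.arange(len(df)), clones.codes] = 1.0
    rep_f = pd.Categorical(df["loc_year"].astype(str) + "/" + df["rep"].astype(str))
    Zr = np.zeros((len(df), len(rep_f.categories)))
    Zr[np.arange(len(df)), rep_f.codes] = 1.0

    res = reml_fit(y, X, [RandomTerm("clone", Zc), RandomTerm("rep", Zr)],
                   max_iter=max_iter)
    s2c = res.variance_components["clone"]
    blup = res.u["clone"]
    pev = res.pev["clone"]
    rel = 1.0 - pev / s2c if s2c > 0 else np.zeros_like(pev)
    records = pd.DataFrame({"clone": list(clones.categories), "blup": blup,
                            "pev": pev, "reliability": rel})
    fixed = pd.Series(np.concatenate([[0.0], res.beta[1:]]),
                      index=list(ly.categories), name="loc_year_effect")
    return Stage1Fit(s2c, res.variance_components["rep"], res.sigma2_e,
                     float(res.beta[0]), fixed, records, res.loglik, trait)


def deregress(fit: Stage1Fit, reliability_floor: float = 0.05) -> pd.DataFrame:
    """Deregressed BLUPs: blup / (1 − PEV/σ̂²_c).

    Records whose reliability falls below ``reliability_floor`` are excluded
    (deregression divides by reliability, which blows up as PEV → σ̂²_c).
    Returns columns clone, blup, pev, reliability, dblup.
    """
    if fit.sigma2_c <= 0:
        raise ValueError("clonal variance is zero; nothing to deregress")
    rec = fit.records.copy()
    keep = rec["reliability"] >= reliability_floor
    n_drop = int((~keep).sum())
    if n_drop == len(rec):
        raise ValueError("every clone has PEV >= clonal variance; "
                         "no usable deregressed records")
    if n_drop:
        logger.info("deregress: excluded %d clone(s) below the reliability "
                    "floor %.3g", n_drop, reliability_floor)
    rec = rec[keep].copy()
    rec["dblup"] = rec["blup"] / rec["reliability"]
    return rec.reset_index(drop=True)
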