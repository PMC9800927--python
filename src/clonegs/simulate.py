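"""Synthetic germplasm panels with controlled additive/dominance architecture.

The generator emulates the structure of a clonal evaluation programme: a
heterozygous germplasm panel genotyped at thousands of biallelic SNPs and
phenotyped in many unbalanced location-year trials with replicate structure.
Trait profiles span the architectures seen in cassava root traits —
dominance-dominated yield (``FRY_like``, ``DRY_like``) and
additive-dominated quality (``DMC_like``).

Genetic effects are simulated on the classical (orthogonal) dominance
scale, so the additive and dominance variance targets are well-defined and
uncorrelated; marker coefficients are rescaled so the realized variances of
Za and Hd hit their targets exactly. Profile variance targets are expressed
on the clone-mean scale (the scale of deregressed stage-one values): the
plot residual is inflated by the expected number of plots per clone so that
a clone's deregressed record is approximately its genotypic value plus
noise of the target residual variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, MarkerDesigns, build_designs, from_dosages
from .stage_one import dmc_from_weights

# (sigma2_a, sigma2_d, sigma2_e) on the clone-mean scale; the yield profiles
# are dominance-dominated (h2 ~ 0.14-0.18, H2 ~ 0.37-0.39), the dry-matter
# profile additive-dominated (h2 ~ 0.48, H2 ~ 0.52).
PROFILES = {
    "FRY_like": {"sigma2_a": 6.4, "sigma2_d": 11.5, "sigma2_e": 28.5,
                 "mu": 20.0, "trait": "fry_tha"},
    "DRY_like": {"sigma2_a": 0.71, "sigma2_d": 0.79, "sigma2_e": 2.55,
                 "mu": 6.0, "trait": "fry_tha"},
    "DMC_like": {"sigma2_a": 1.92, "sigma2_d": 0.18, "sigma2_e": 1.92,
                 "mu": 27.0, "trait": "dmc"},
}


@dataclass
class SimConfig:
    """Panel and trial dimensions plus the trait architecture."""

    n_clones: int = 900
    m_markers: int = 3000
    maf_range: tuple = (0.05, 0.95)
    family_size: int = 6  # full-sib group size; 1 = unrelated clones
    n_founders: int | None = None  # default: n_clones // 10 (min 20)
    profile: str = "FRY_like"
    sigma2_a: float | None = None  # clone-mean scale overrides
    sigma2_d: float | None = None
    sigma2_e: float | None = None
    mu: float | None = None
    n_location_years: int = 20
    n_reps: int = 3
    incidence_rate: float = 0.3  # fraction of trials each clone is planted in
    missing_plot_rate: float = 0.02
    trial_effect_sd: float | None = None  # default: genetic SD of the trait
    rep_effect_sd: float | None = None  # default: 0.3 x genetic SD
    inbreeding_F: float = 0.0  # negative = excess heterozygosity
    seed: int = 0

    def resolved(self) -> dict:
        if self.profile not in PROFILES and self.profile != "custom":
            raise ValueError(f"unknown trait profile {self.profile!r}")
        base = dict(PROFILES.get(self.profile, PROFILES["FRY_like"]))
        for k in ("sigma2_a", "sigma2_d", "sigma2_e", "mu"):
            v = getattr(self, k)
            if v is not None:
                base[k] = float(v)
        for k in ("sigma2_a", "sigma2_d", "sigma2_e"):
            if base[k] < 0:
                raise ValueError(f"{k} must be non-negative")
        return base

    @property
    def trials_per_clone(self) -> int:
        return max(1, round(self.n_location_years * self.incidence_rate))

    @property
    def expected_plots_per_clone(self) -> float:
        return self.trials_per_clone * self.n_reps \
            * (1.0 - self.missing_plot_rate)


@dataclass
class TrueValues:
    """Simulated truth: per-clone breeding values, dominance deviations and
    genotypic values, plus the marker coefficients that generated them."""

    breeding: np.ndarray
    dominance: np.ndarray
    alpha: np.ndarray
    delta: np.ndarray
    clone_ids: np.ndarray
    targets: dict

    @property
    def genotypic(self) -> np.ndarray:
        return self.breeding + self.dominance


def _hwe_dosages(rng, p, n, F=0.0):
    f_mm = (1 - p) ** 2 + F * p * (1 - p)
    f_het = 2 * p * (1 - p) * (1 - F)
    probs = np.clip(np.stack([f_mm, f_het, 1 - f_mm - f_het]), 0, 1)
    probs /= probs.sum(axis=0)
    u = rng.random((n, len(p)))
    return (u > probs[0]).astype(float) + (u > probs[0] + probs[1])


def simulate_genotypes(cfg: SimConfig, rng=None) -> GenotypeMatrix:
    """Panel genotypes at frequencies drawn uniformly from ``maf_range``.

    With ``family_size`` = 1 every clone is an independent HWE draw. The
    default emulates the relatedness present in real germplasm collections:
    founders are HWE draws (optionally perturbed by inbreeding F) and
    clones come in full-sib groups, each marker transmitted as a Bernoulli
    gamete from each parent (unlinked loci). Marginal genotype frequencies
    stay Hardy–Weinberg; pairwise relationships now vary, which is what
    lets marker-based REML partition additive from dominance variance.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    p = rng.uniform(*cfg.maf_range, cfg.m_markers)
    if cfg.family_size <= 1:
        dosages = _hwe_dosages(rng, p, cfg.n_clones, cfg.inbreeding_F)
    else:
        n_found = cfg.n_founders or max(20, cfg.n_clones // 10)
        founders = _hwe_dosages(rng, p, n_found, cfg.inbreeding_F)
        n_fam = -(-cfg.n_clones // cfg.family_size)
        pairs = np.array([rng.choice(n_found, 2, replace=False)
                          for _ in range(n_fam)])
        rows = []
        for sire, dam in pairs:
            ga = rng.random((cfg.family_size, cfg.m_markers)) < founders[sire] / 2.0
            gb = rng.random((cfg.family_size, cfg.m_markers)) < founders[dam] / 2.0
            rows.append(ga.astype(float) + gb.astype(float))
        dosages = np.vstack(rows)[:cfg.n_clones]
    clone_ids = np.array([f"C{i:04d}" for i in range(cfg.n_clones)])
    marker_ids = np.array([f"M{j:05d}" for j in range(cfg.m_markers)])
    g = from_dosages(clone_ids, marker_ids, dosages)
    poly = g.maf() > 0  # family sampling can fix an allele; drop such markers
    if not poly.all():
        g = GenotypeMatrix(g.clone_ids, g.marker_ids[poly],
                           g.dosages[:, poly], g.p[poly])
    return g


def simulate_effects(g: GenotypeMatrix, cfg: SimConfig, rng=None) -> TrueValues:
    """Draw i.i.d. normal marker coefficients on the classical scale and
    rescale them so realized VAR(Za) and VAR(Hd) equal the targets exactly."""
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    tg = cfg.resolved()
    designs = build_designs(g, center_additive=True)

    def scaled(X, target):
        if target == 0:
            return np.zeros(X.shape[1]), np.zeros(X.shape[0])
        coef = rng.normal(size=X.shape[1])
        vals = X @ coef
        v = vals.var(ddof=1)
        if v <= 0:
            raise ValueError("degenerate design; cannot reach variance target")
        c = np.sqrt(target / v)
        return coef * c, vals * c

    alpha, breeding = scaled(designs.Z_add, tg["sigma2_a"])
    delta, dominance = scaled(designs.H_classical, tg["sigma2_d"])
    return TrueValues(breeding, dominance, alpha, delta,
                      np.asarray(g.clone_ids), tg)


def simulate_trials(true: TrueValues, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Plot records y = μ + β_trial + r_rep + g_clone + ε over an unbalanced
    clone × trial incidence.

    Each clone is planted in a fixed number of randomly chosen trials
    (``incidence_rate`` × the number of trials), so trials differ in
    composition (unbalanced) while every clone carries comparable
    information — the regime in which deregressed records behave like
    g + N(0, σ²_e target). The plot residual SD is the clone-mean-scale
    target inflated by the expected plots per clone. DMC-profile plots are
    emitted as WA/WW weighings back-solved so ``dmc_from_weights`` recovers
    the simulated plot value exactly; plot values below the smallest DMC a
    non-negative water weight can encode (≈16.3%) are clipped to 16.5% first.
    Yield profiles emit fry_tha.
    """
    rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    tg = true.targets
    n = len(true.clone_ids)
    sigma2_plot = tg["sigma2_e"] * max(cfg.expected_plots_per_clone, 1.0)
    gen_sd = np.sqrt(tg["sigma2_a"] + tg["sigma2_d"]) or 1.0
    trial_sd = cfg.trial_effect_sd if cfg.trial_effect_sd is not None else gen_sd
    rep_sd = cfg.rep_effect_sd if cfg.rep_effect_sd is not None else 0.3 * gen_sd
    locs = [f"L{t % 2}" for t in range(cfg.n_location_years)]
    years = [2011 + t // 2 for t in range(cfg.n_location_years)]
    beta = rng.normal(0, trial_sd, cfg.n_location_years)
    g = true.genotypic

    # each clone gets trials_per_clone trials, drawn uniformly
    k = min(cfg.trials_per_clone, cfg.n_location_years)
    draws = rng.random((n, cfg.n_location_years)).argsort(axis=1)[:, :k]
    planted = np.zeros((n, cfg.n_location_years), dtype=bool)
    np.put_along_axis(planted, draws, True, axis=1)

    rows = []
    for t in range(cfg.n_location_years):
        idx = np.flatnonzero(planted[:, t])
        for rep in range(1, cfg.n_reps + 1):
            r_eff = rng.normal(0, rep_sd)
            keep = rng.random(len(idx)) >= cfg.missing_plot_rate
            sel = idx[keep]
            eps = rng.normal(0, np.sqrt(sigma2_plot), len(sel))
            y = tg["mu"] + beta[t] + r_eff + g[sel] + eps
            rows.append(pd.DataFrame({
                "clone": true.clone_ids[sel], "location": locs[t],
                "year": years[t], "rep": rep, "value": y}))
    df = pd.concat(rows, ignore_index=True)

    if tg["trait"] == "dmc":
        # back-solve WA/WW from the plot DMC: WA/(WA-WW) = (DMC+142)/158.3;
        # WW >= 0 requires DMC >= 16.3, so clip the (rare) low tail
        dmc = np.clip(df["value"].to_numpy(), 16.5, 95.0)
        c = (dmc + 142.0) / 158.3
        wa = np.full(len(df), 5.0)
        df["wa_kg"] = wa
        df["ww_kg"] = wa * (1.0 - 1.0 / c)
        df = df.drop(columns="value")
    else:
        df["fry_tha"] = df.pop("value")
    return df


def simulate_dataset(cfg: SimConfig):
    """Convenience: genotypes, true values and trial table in one call,
    plus a manifest of the conditions used."""
    g = simulate_genotypes(cfg)
    true = simulate_effects(g, cfg)
    trials = simulate_trials(true, cfg)
    tg = true.targets
    s2g = tg["sigma2_a"] + tg["sigma2_d"]
    manifest = {
        "config": asdict(cfg), "targets": tg,
        "target_h2": tg["sigma2_a"] / (s2g + tg["sigma2_e"]),
        "target_H2": s2g / (s2g + tg["sigma2_e"]),
    }
    return g, true, trials, manifest


def write_dataset(outdir, g: GenotypeMatrix, trials: pd.DataFrame,
                  manifest: dict) -> None:
    """Emit the TSV/CSV dialects the pipeline consumes plus a manifest."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno = pd.DataFrame(g.dosages.astype(int), index=g.clone_ids,
                        columns=g.marker_ids)
    geno.index.name = "clone"
    geno.to_csv(outdir / "genotypes.tsv", sep="\t")
    trials.to_csv(outdir / "phenotypes.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
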