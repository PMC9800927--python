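"""File-based pipeline stages: simulate → stage1 → kinship → fit → cv →
select → report.

Each stage reads the previous stage's plain-text artifacts from a run
directory, writes its own outputs plus a ``<stage>.manifest.json`` (settings,
seed, input hashes), and is individually re-runnable. All randomness flows
from one root seed expanded per stage.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossval, gblup, kinship, selection
from .bayes import McmcConfig, run_bayesCpi
from .genotypes import build_designs, impute_mean, load_genotypes, quality_filter
from .simulate import SimConfig, simulate_dataset, write_dataset
from .stage_one import deregress, derive_traits, fit_stage1

STAGE_SEEDS = {"simulate": 11, "cv": 29, "mcmc": 41}


class MissingArtifact(FileNotFoundError):
    pass


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifact(
            f"missing {path.name}; run the '{stage}' stage first")
    return path


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_manifest(outdir: Path, stage: str, cfg: dict, inputs=()):
    entry = {
        "stage": stage, "config": cfg, "config_hash": _config_hash(cfg),
        "input_hashes": {
            str(p): hashlib.sha256(Path(p).read_bytes()).hexdigest()[:12]
            for p in inputs},
    }
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps(entry, indent=2, default=str))


def cmd_simulate(outdir, seed: int = 0, **sim_kwargs) -> Path:
    outdir = Path(outdir)
    cfg = SimConfig(seed=seed + STAGE_SEEDS["simulate"], **sim_kwargs)
    g, true, trials, manifest = simulate_dataset(cfg)
    write_dataset(outdir, g, trials, manifest)
    _write_manifest(outdir, "simulate", manifest["config"])
    return outdir


def cmd_stage1(outdir, trait: str, reliability_floor: float = 0.05) -> Path:
    outdir = Path(outdir)
    pheno = _require(outdir / "phenotypes.csv", "simulate")
    table = derive_traits(pd.read_csv(pheno))
    col = {"FRY": "fry_tha", "DMC": "dmc_pct", "DRY": "dry_tha"}.get(trait, trait)
    fit = fit_stage1(table, col)
    rec = deregress(fit, reliability_floor)
    out = outdir / f"stage1_{trait}.tsv"
    rec.to_csv(out, sep="\t", index=False)
    comps = {"sigma2_c": fit.sigma2_c, "sigma2_r": fit.sigma2_r,
             "sigma2_e": fit.sigma2_e, "H2_pheno": fit.H2_pheno,
             "mu": fit.mu, "trait": trait}
    (outdir / f"stage1_{trait}.components.json").write_text(
        json.dumps(comps, indent=2))
    _write_manifest(outdir, f"stage1_{trait}",
                    {"trait": trait, "reliability_floor": reliability_floor},
                    [pheno])
    return out


def _load_kinships(outdir: Path):
    mats = {}
    for kind in kinship.KINDS:
        f = _require(outdir / f"kinship_{kind}.tsv", "kinship")
        df = pd.read_csv(f, sep="\t", index_col=0)
        mats[kind] = kinship.RelationshipMatrix(
            kind, df.to_numpy(), df.index.to_numpy(), float("nan"))
    return mats


def cmd_kinship(outdir, min_call_rate: float = 0.90, min_maf: float = 0.05,
                h: float = 1.0) -> Path:
    outdir = Path(outdir)
    geno_path = _require(outdir / "genotypes.tsv", "simulate")
    g = impute_mean(quality_filter(load_genotypes(geno_path),
                                   min_call_rate, min_maf))
    designs = build_designs(g)
    mats = {
        "additive": kinship.additive_G(designs),
        "dom_classical": kinship.dominance_classical(designs),
        "dom_genotypic": kinship.dominance_genotypic(designs),
        "gaussian_kernel": kinship.gaussian_kernel(g, h=h),
    }
    for kind, rm in mats.items():
        kinship.condition_psd(rm).to_frame().to_csv(
            outdir / f"kinship_{kind}.tsv", sep="\t")
    _write_manifest(outdir, "kinship",
                    {"min_call_rate": min_call_rate, "min_maf": min_maf, "h": h},
                    [geno_path])
    return outdir


def _aligned_cvdata(outdir: Path, trait: str, mcmc: McmcConfig) -> crossval.CVData:
    s1 = pd.read_csv(_require(outdir / f"stage1_{trait}.tsv", "stage1"), sep="\t")
    mats = _load_kinships(outdir)
    clone_ids = np.asarray(mats["additive"].clone_ids)
    s1 = s1.set_index("clone").reindex(clone_ids).dropna(subset=["dblup"])
    keep = np.isin(clone_ids, s1.index.to_numpy())
    idx = np.flatnonzero(keep)
    sub = {k: kinship.condition_psd(kinship.RelationshipMatrix(
               k, m.values[np.ix_(idx, idx)], clone_ids[idx],
               m.scaling_constant))
           for k, m in mats.items()}
    g = impute_mean(quality_filter(load_genotypes(outdir / "genotypes.tsv")))
    order = [np.flatnonzero(g.clone_ids == c)[0] for c in clone_ids[idx]]
    from .genotypes import GenotypeMatrix

    gsub = GenotypeMatrix(g.clone_ids[order], g.marker_ids,
                          g.dosages[order], g.p, imputed=True)
    designs = build_designs(gsub)
    return crossval.CVData(clone_ids[idx], s1["dblup"].to_numpy(),
                           s1["blup"].to_numpy(), sub, designs, mcmc)


def cmd_cv(outdir, trait: str, methods=crossval.METHODS, n_folds: int = 5,
           n_reps: int = 3, seed: int = 0, mcmc: McmcConfig | None = None,
           estimate_pi: bool = True) -> Path:
    """Shared-plan cross-validation for the listed methods; when Bayes
    methods are requested, their π prior defaults to a Bayes Cπ estimate
    computed on the full data first."""
    outdir = Path(outdir)
    bad = [m for m in methods if m not in crossval.METHODS]
    if bad:
        raise ValueError(f"unknown method(s) {bad}; valid: {list(crossval.METHODS)}")
    mcmc = mcmc or McmcConfig()
    data = _aligned_cvdata(outdir, trait, mcmc)
    if estimate_pi and any(m.startswith("BayesB") for m in methods):
        from dataclasses import replace

        cpi = run_bayesCpi(data.dblup, data.designs,
                           replace(mcmc, seed=seed + STAGE_SEEDS["mcmc"]),
                           with_dominance=True)
        data.mcmc = replace(mcmc, pi=min(cpi.pi_a, 1 - 1e-6),
                            pi_dom=min(cpi.pi_d, 1 - 1e-6))
    plan = crossval.make_plan(data.clone_ids, n_folds, n_reps,
                              seed + STAGE_SEEDS["cv"])
    results = pd.concat([crossval.evaluate(m, plan, data) for m in methods],
                        ignore_index=True)
    out = outdir / f"cv_{trait}.tsv"
    results.to_csv(out, sep="\t", index=False)
    _write_manifest(outdir, f"cv_{trait}",
                    {"trait": trait, "methods": list(methods), "seed": seed,
                     "n_folds": n_folds, "n_reps": n_reps,
                     "mcmc": data.mcmc.__dict__},
                    [outdir / f"stage1_{trait}.tsv"])
    return out


def cmd_fit(outdir, trait: str, model: str = "GBLUP_AD_classical",
            mcmc: McmcConfig | None = None, seed: int = 0) -> Path:
    """Full-data fit of one method; writes components + per-clone solutions."""
    outdir = Path(outdir)
    data = _aligned_cvdata(outdir, trait, mcmc or McmcConfig())
    train = np.ones(len(data.clone_ids), dtype=bool)
    pred = crossval._predict_fold(model, data, train, seed + STAGE_SEEDS["mcmc"])
    sol = pd.DataFrame({"clone": data.clone_ids, "prediction": pred,
                        "blup": data.blup, "dblup": data.dblup})
    out = outdir / f"fit_{trait}_{model}.tsv"
    sol.to_csv(out, sep="\t", index=False)
    if model.startswith(("GBLUP", "RKHS")):
        y = data.dblup.astype(float)
        spec = gblup.ModelSpec(y, data.clone_ids,
                               crossval._gblup_terms(model, data))
        fit = gblup.fit_gblup(spec)
        h2, H2 = gblup.heritabilities(fit)
        (outdir / f"fit_{trait}_{model}.components.json").write_text(
            json.dumps({"variance_components": fit.variance_components,
                        "sigma2_e": fit.sigma2_e, "h2": h2, "H2": H2},
                       indent=2))
    _write_manifest(outdir, f"fit_{trait}_{model}",
                    {"trait": trait, "model": model, "seed": seed},
                    [outdir / f"stage1_{trait}.tsv"])
    return out


def cmd_select(outdir, trait: str, models=("GBLUP_AD_classical",),
               grid: selection.SelectionGrid | None = None) -> Path:
    outdir = Path(outdir)
    rankings, merit, ids = {}, None, None
    for model in models:
        f = _require(outdir / f"fit_{trait}_{model}.tsv", "fit")
        df = pd.read_csv(f, sep="\t")
        rankings[model] = df["prediction"].to_numpy()
        merit, ids = df["blup"].to_numpy(), df["clone"].to_numpy()
    rep = selection.selection_report(rankings, merit, grid, ids, trait)
    rep.to_csv(outdir / f"selection_{trait}.tsv", sep="\t", index=False)
    kap = selection.kappa_report(rankings, grid, ids, merit)
    kap.to_csv(outdir / f"kappa_{trait}.tsv", sep="\t", index=False)
    _write_manifest(outdir, f"select_{trait}",
                    {"trait": trait, "models": list(models)})
    return outdir / f"selection_{trait}.tsv"


def cmd_report(outdir, trait: str, make_plot: bool = False) -> Path:
    """Aggregate CV results into a method-comparison table (LRT + Tukey
    letters) and optional boxplots."""
    outdir = Path(outdir)
    results = pd.read_csv(_require(outdir / f"cv_{trait}.tsv", "cv"), sep="\t")
    lines = []
    for value in ("r", "b"):
        cmp_ = crossval.compare_methods(results, value=value)
        tab = cmp_.means.copy()
        tab.insert(0, "statistic", value)
        tab["chi2"] = cmp_.chi2
        tab["p_value"] = cmp_.p_value
        lines.append(tab.reset_index())
    rep = pd.concat(lines, ignore_index=True)
    out = outdir / f"report_{trait}.tsv"
    rep.to_csv(out, sep="\t", index=False)
    if make_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for ax, value in zip(axes, ("r", "b")):
            results.boxplot(column=value, by="method", ax=ax, rot=45)
            ax.set_title(f"{trait}: {value}")
        fig.suptitle("")
        fig.tight_layout()
        fig.savefig(outdir / f"report_{trait}.png", dpi=120)
        plt.close(fig)
    _write_manifest(outdir, f"report_{trait}", {"trait": trait})
    return out
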