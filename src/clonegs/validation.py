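"""Self-validation experiments: the checks that certify the pipeline.

Each function runs one end-to-end experiment on synthetic data and returns
plain numbers, so the same battery can back both the test suite and a
reproduction script:

* G-BLUP vs SNP-BLUP equivalence on a small instance (exact MME identity);
* heritability recovery — simulate a panel under a trait profile, run
  stage one, deregression and A+D G-BLUP, compare ĥ²/Ĥ² medians to the
  profile targets;
* directional cross-validation — additive vs additive-dominant predictive
  ability under dominance-dominated and additive-dominated architectures;
* Bayes B null calibration and Raftery–Lewis chain calibration;
* exhaustive Cohen-kappa agreement against the 2×2-table definition;
* the normal-theory selection-intensity check.
"""

from __future__ import annotations

from math import ceil

import numpy as np

from . import kinship as kin
from .bayes import McmcConfig, run_bayesB
from .crossval import CVData, evaluate, make_plan
from .diagnostics import raftery_lewis
from .gblup import ModelSpec, fit_gblup, heritabilities
from .genotypes import MarkerDesigns, build_designs, from_dosages, impute_mean
from .mixed_model import RandomTerm, mme_solve
from .selection import cohen_kappa, selection_differential
from .simulate import SimConfig, simulate_dataset
from .stage_one import deregress, derive_traits, fit_stage1


def _subset(mat, idx, ids):
    return kin.condition_psd(kin.RelationshipMatrix(
        mat.kind, mat.values[np.ix_(idx, idx)], np.asarray(ids),
        mat.scaling_constant))


def panel_stage_two_inputs(profile: str, seed: int, n=600, m=3000,
                           n_trials=6, n_reps=3, incidence=0.75,
                           kinds=("additive", "dom_classical"),
                           with_designs=False):
    """Simulate a panel, run stage one + deregression, and assemble the
    aligned kinships (and optionally marker designs) for stage two."""
    cfg = SimConfig(n_clones=n, m_markers=m, n_location_years=n_trials,
                    n_reps=n_reps, incidence_rate=incidence, profile=profile,
                    seed=seed)
    g, true, trials, manifest = simulate_dataset(cfg)
    col = "dmc_pct" if true.targets["trait"] == "dmc" else "fry_tha"
    fit1 = fit_stage1(derive_traits(trials), col)
    rec = deregress(fit1)
    designs = build_designs(impute_mean(g))
    ids = rec["clone"].to_numpy()
    idx = np.array([np.flatnonzero(g.clone_ids == c)[0] for c in ids])
    ctors = {"additive": kin.additive_G, "dom_classical": kin.dominance_classical,
             "dom_genotypic": kin.dominance_genotypic}
    mats = {}
    for kind in kinds:
        if kind == "gaussian_kernel":
            mats[kind] = _subset(kin.gaussian_kernel(impute_mean(g)), idx, ids)
        else:
            mats[kind] = _subset(ctors[kind](designs), idx, ids)
    sub_designs = None
    if with_designs:
        sub_designs = MarkerDesigns(designs.Z_add[idx],
                                    designs.H_classical[idx],
                                    designs.H_genotypic[idx], designs.p,
                                    ids, designs.coding_note)
    data = CVData(ids, rec["dblup"].to_numpy(), rec["blup"].to_numpy(),
                  mats, sub_designs)
    return data, manifest


def gblup_snpblup_max_diff(seed: int = 3, n: int = 8, m: int = 4) -> float:
    """Largest absolute difference between G-BLUP and marker-effect ridge
    solutions at matched variance ratios, for the A and A+D models."""
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, (n, m)).astype(float)
    g = from_dosages([f"c{i}" for i in range(n)],
                     [f"m{j}" for j in range(m)], dos, orient_major=False)
    d = build_designs(g)
    y = rng.normal(0, 2, n)
    Z, H, p = d.Z_add, d.H_classical, d.p
    ca = 2 * np.sum(p * (1 - p))
    cd = np.sum((2 * p * (1 - p)) ** 2)
    eye = np.eye(n)
    G = Z @ Z.T / ca + 1e-10 * eye
    D = H @ H.T / cd + 1e-10 * eye
    X = np.ones((n, 1))
    worst = 0.0
    gb = mme_solve(y, X, [RandomTerm("a", eye, G)],
                   {"a": 1.7, "residual": 0.9})
    rr = mme_solve(y, X, [RandomTerm("m", Z)],
                   {"m": 1.7 / ca, "residual": 0.9})
    worst = max(worst, float(np.abs(gb.u["a"] - Z @ rr.u["m"]).max()))
    gb2 = mme_solve(y, X, [RandomTerm("a", eye, G), RandomTerm("d", eye, D)],
                    {"a": 1.3, "d": 0.8, "residual": 1.1})
    rr2 = mme_solve(y, X, [RandomTerm("am", Z), RandomTerm("dm", H)],
                    {"am": 1.3 / ca, "dm": 0.8 / cd, "residual": 1.1})
    worst = max(worst, float(np.abs(
        gb2.u["a"] + gb2.u["d"] - (Z @ rr2.u["am"] + H @ rr2.u["dm"])).max()))
    return worst


def heritability_recovery(profile: str, seeds, n=600, m=3000) -> dict:
    """Median recovered (ĥ², Ĥ²) from the full two-stage pipeline with the
    A+D classical model, against the profile targets."""
    h2s, H2s = [], []
    target_h2 = target_H2 = None
    for seed in seeds:
        data, manifest = panel_stage_two_inputs(profile, seed, n=n, m=m)
        spec = ModelSpec(data.dblup.astype(float), data.clone_ids,
                         [(data.kinships["additive"], "additive"),
                          (data.kinships["dom_classical"], "dominance")])
        h2, H2 = heritabilities(fit_gblup(spec))
        h2s.append(h2)
        H2s.append(H2)
        target_h2, target_H2 = manifest["target_h2"], manifest["target_H2"]
    return {"h2_median": float(np.median(h2s)),
            "H2_median": float(np.median(H2s)),
            "h2_target": target_h2, "H2_target": target_H2,
            "h2": h2s, "H2": H2s}


def cv_directional(profile: str, seeds, n=600, m=3000) -> dict:
    """Mean 5×3-CV predictive ability of G-BLUP A vs A+D classical, pooled
    over seeds (shared plan per seed)."""
    rA, rAD = [], []
    for seed in seeds:
        data, _ = panel_stage_two_inputs(profile, seed, n=n, m=m)
        plan = make_plan(data.clone_ids, 5, 3, seed=seed * 7 + 1)
        rA.append(evaluate("GBLUP_A", plan, data)["r"].mean())
        rAD.append(evaluate("GBLUP_AD_classical", plan, data)["r"].mean())
    return {"r_additive": float(np.mean(rA)),
            "r_additive_dominant": float(np.mean(rAD)),
            "difference": float(np.mean(rAD) - np.mean(rA))}


def bayesb_null_inclusion(seed: int, n=200, m=1000, n_iter=5000) -> float:
    """Mean posterior inclusion probability of Bayes B on pure-noise data
    at π = 0.99 (should be far below 0.05)."""
    cfg = SimConfig(n_clones=n, m_markers=m, seed=seed, family_size=1)
    from .simulate import simulate_genotypes

    g = simulate_genotypes(cfg)
    designs = build_designs(impute_mean(g))
    rng = np.random.default_rng(seed + 1)
    y = rng.normal(0, 1, n)
    post = run_bayesB(y, designs,
                      McmcConfig(n_iter=n_iter, burn_in=n_iter // 5, thin=5,
                                 seed=seed, pi=0.99))
    return float(post.inclusion_a.mean())


def raftery_factors(seed: int, n_iid=30000, n_ar=60000, rho=0.95) -> dict:
    rng = np.random.default_rng(seed)
    iid = rng.normal(size=n_iid)
    ar = np.empty(n_ar)
    ar[0] = 0.0
    eps = rng.normal(size=n_ar)
    for i in range(1, n_ar):
        ar[i] = rho * ar[i - 1] + eps[i]
    return {"iid": raftery_lewis(iid).dependence_factor,
            "ar1": raftery_lewis(ar).dependence_factor}


def _kappa_from_table(n11, n10, n01, n00) -> float:
    n = n11 + n10 + n01 + n00
    po = (n11 + n00) / n
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


def kappa_exhaustive_max_err(n_max: int = 12) -> float:
    """Exhaustively compare cohen_kappa against the 2×2-table definition
    over every table with n ≤ n_max."""
    worst = 0.0
    for n in range(2, n_max + 1):
        for n11 in range(n + 1):
            for n10 in range(n - n11 + 1):
                for n01 in range(n - n11 - n10 + 1):
                    n00 = n - n11 - n10 - n01
                    a = np.array([1] * n11 + [1] * n10 + [0] * n01 + [0] * n00)
                    b = np.array([1] * n11 + [0] * n10 + [1] * n01 + [0] * n00)
                    worst = max(worst, abs(
                        cohen_kappa(a, b) -
                        _kappa_from_table(n11, n10, n01, n00)))
    return worst


def selection_intensity(sp: float = 0.05, n: int = 100_000,
                        seed: int = 0) -> float:
    """Selection differential of a standard-normal merit under perfect
    ranking, i.e. the empirical selection intensity i(sp)."""
    merit = np.random.default_rng(seed).normal(0, 1, n)
    return float(selection_differential(merit, merit, sp))
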