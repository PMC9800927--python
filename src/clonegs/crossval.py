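"""Seeded k-fold cross-validation shared across prediction methods.

One :class:`CVPlan` (5 folds × 3 repetitions by default) is served to every
method so predictive abilities are compared on identical partitions; each
result row carries the plan hash as a guard. Per (method, rep, fold):

* predictive ability r̂ = COR(pred_validation, BLUP_validation), the
  correlation between held-out predictions (GEBV for additive models, GEGV
  for additive-dominant and kernel models) and the stage-one BLUPs of the
  validation clones;
* bias b̂ = COV(pred_train, BLUP_train)/VAR(pred_train), a dispersion
  coefficient computed on the training partition (1 = unbiased).

Methods are compared with a mixed model (method fixed, rep × fold block
random) — a likelihood-ratio χ² for the method effect and Tukey's HSD on
the method means with a compact letter display.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import McmcConfig, run_bayesB, run_bayesCpi
from .gblup import FitResult, ModelSpec, fit_gblup
from .genotypes import MarkerDesigns
from .kinship import RelationshipMatrix

METHODS = ("GBLUP_A", "GBLUP_AD_classical", "GBLUP_AD_genotypic", "RKHS",
           "BayesB_A", "BayesB_AD")


@dataclass
class CVPlan:
    """Fold assignment per clone per repetition; deterministic given seed."""

    clone_ids: np.ndarray
    n_folds: int
    n_reps: int
    seed: int
    assignments: np.ndarray  # (n_reps, n_clones) fold indices

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.assignments.tobytes()).hexdigest()[:16]

    def fold_mask(self, rep: int, fold: int) -> np.ndarray:
        return self.assignments[rep] == fold


def make_plan(clone_ids, n_folds: int = 5, n_reps: int = 3,
              seed: int = 0) -> CVPlan:
    """Balanced fold assignment (sizes differ by at most one)."""
    clone_ids = np.asarray(clone_ids)
    n = len(clone_ids)
    if n < n_folds:
        raise ValueError("fewer clones than folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_reps, n), dtype=np.int64)
    base = np.arange(n) % n_folds
    for rep in range(n_reps):
        assignments[rep] = base[rng.permutation(n)]
    return CVPlan(clone_ids, n_folds, n_reps, seed, assignments)


@dataclass
class CVData:
    """Everything a method needs: response, merit, kinships and designs."""

    clone_ids: np.ndarray
    dblup: np.ndarray  # stage-one deregressed BLUPs (the stage-two response)
    blup: np.ndarray  # stage-one BLUPs (the validation/training merit)
    kinships: dict = field(default_factory=dict)  # kind label -> RelationshipMatrix
    designs: MarkerDesigns | None = None  # for the Bayes methods
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    validate_against: str = "blup"  # or "dblup"

    def merit(self) -> np.ndarray:
        return self.blup if self.validate_against == "blup" else self.dblup


def _gblup_terms(method: str, data: CVData):
    k = data.kinships
    if method == "GBLUP_A":
        return [(k["additive"], "additive")]
    if method == "GBLUP_AD_classical":
        return [(k["additive"], "additive"), (k["dom_classical"], "dominance")]
    if method == "GBLUP_AD_genotypic":
        return [(k["additive"], "additive"), (k["dom_genotypic"], "dominance")]
    if method == "RKHS":
        return [(k["gaussian_kernel"], "genotypic")]
    raise KeyError(method)


def _predict_fold(method: str, data: CVData, train: np.ndarray,
                  seed: int) -> np.ndarray:
    """Fit on the training clones, return predictions for every clone
    (GEBV for additive models, GEGV otherwise)."""
    y = data.dblup.astype(float).copy()
    y[~train] = np.nan
    if method.startswith(("GBLUP", "RKHS")):
        spec = ModelSpec(y, data.clone_ids, _gblup_terms(method, data))
        fit = fit_gblup(spec)
        return fit.gebv if method == "GBLUP_A" else fit.gegv
    if method in ("BayesB_A", "BayesB_AD"):
        if data.designs is None:
            raise ValueError("Bayes methods need marker designs in CVData")
        with_dom = method.endswith("AD")
        d = data.designs
        sub = MarkerDesigns(d.Z_add[train], d.H_classical[train],
                            d.H_genotypic[train], d.p,
                            data.clone_ids[train], d.coding_note)
        from dataclasses import replace

        post = run_bayesB(data.dblup[train], sub,
                          replace(data.mcmc, seed=seed), with_dominance=with_dom)
        pred = post.predict(d.Z_add, d.H_classical)
        return pred["gebv"] if method == "BayesB_A" else pred["gegv"]
    raise ValueError(f"unknown method {method!r}; valid: {METHODS}")


def evaluate(method: str, plan: CVPlan, data: CVData) -> pd.DataFrame:
    """Run one method over every (rep, fold); returns tidy rows with the
    plan hash, predictive ability r and training bias b."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {METHODS}")
    if not np.array_equal(plan.clone_ids, data.clone_ids):
        raise ValueError("plan and data cover different clones")
    merit = data.merit()
    rows = []
    for rep in range(plan.n_reps):
        for fold in range(plan.n_folds):
            val = plan.fold_mask(rep, fold)
            train = ~val
            seed = plan.seed * 100003 + rep * 101 + fold
            pred = _predict_fold(method, data, train, seed % (2**31 - 1))
            r = float(np.corrcoef(pred[val], merit[val])[0, 1])
            vp = np.var(pred[train], ddof=1)
            if vp <= 0:
                warnings.warn(f"{method} rep{rep} fold{fold}: zero prediction "
                              "variance; bias undefined")
                b = np.nan
            else:
                b = float(np.cov(pred[train], merit[train], ddof=1)[0, 1] / vp)
            rows.append({"method": method, "rep": rep, "fold": fold,
                         "r": r, "b": b, "plan_hash": plan.hash})
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    return (results.groupby("method")[["r", "b"]]
            .mean().rename(columns={"r": "mean_r", "b": "mean_b"}))


@dataclass
class MethodComparison:
    statistic: str
    chi2: float
    df: int
    p_value: float
    significant: bool
    means: pd.DataFrame  # method, mean, letters


def _letters(means: pd.Series, nonsig: np.ndarray) -> pd.Series:
    """Compact letter display from a symmetric non-significance matrix over
    methods sorted by descending mean (equal SEs make non-significance
    interval-like in that order)."""
    order = means.sort_values(ascending=False).index
    k = len(order)
    pos = {m: i for i, m in enumerate(means.index)}  # nonsig's ordering
    ns = np.array([[nonsig[pos[a], pos[b]] for b in order] for a in order])
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, i:j + 2].all() and ns[i:j + 2, i:j + 2].all():
            j += 1
        intervals.append((i, j))
    keep = [iv for iv in intervals
            if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                       for o in intervals)]
    lab = {m: "" for m in order}
    for letter, (i, j) in zip("ABCDEFGHIJKLMNOP", keep):
        for m in order[i:j + 1]:
            lab[m] += letter
    return pd.Series(lab)


def compare_methods(results: pd.DataFrame, value: str = "r",
                    alpha: float = 0.05) -> MethodComparison:
    """Mixed-model comparison of per-fold statistics across methods.

    Fits value ~ method (fixed) with a random rep × fold block via ML and
    tests the method effect with a likelihood-ratio χ²; Tukey's HSD with a
    compact letter display summarizes pairwise differences.
    """
    import statsmodels.formula.api as smf
    from scipy.stats import chi2 as chi2_dist
    from scipy.stats import studentized_range

    df = results.dropna(subset=[value]).copy()
    methods = sorted(df["method"].unique())
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    df["block"] = df["rep"].astype(str) + ":" + df["fold"].astype(str)
    df = df.rename(columns={value: "yy"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = smf.mixedlm("yy ~ C(method)", df, groups="block").fit(reml=False)
        null = smf.mixedlm("yy ~ 1", df, groups="block").fit(reml=False)
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    dof = len(methods) - 1
    p = float(chi2_dist.sf(stat, dof))

    means = df.groupby("method")["yy"].mean()
    counts = df.groupby("method")["yy"].size()
    s2e = float(full.scale)
    df_resid = int(len(df) - len(methods) - df["block"].nunique() + 1)
    k = len(methods)
    nonsig = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(s2e / 2.0 * (1.0 / counts.iloc[i] + 1.0 / counts.iloc[j]))
            qstat = abs(means.iloc[i] - means.iloc[j]) / se
            pq = float(studentized_range.sf(qstat, k, max(df_resid, 2)))
            nonsig[i, j] = nonsig[j, i] = pq > alpha
    letters = _letters(means, nonsig)
    table = pd.DataFrame({"mean": means, "letters": letters}).sort_values(
        "mean", ascending=False)
    return MethodComparison(value, float(stat), dof, p, p <= alpha, table)
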