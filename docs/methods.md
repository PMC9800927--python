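# Methods

## The two-stage evaluation

Stage one fits, per trait, the plot-level mixed model

    y_ijl = μ + c_i + β_j + r_l(j) + ε_ijl

with clone effects `c_i ~ N(0, Iσ²_c)`, fixed location-year combinations
`β_j`, replicates nested in location-year `r_l(j) ~ N(0, Iσ²_r)` and plot
residuals `ε ~ N(0, Iσ²_e)`. Location-years with a single record are
dropped (their fixed effect is confounded with the residual). BLUPs and
PEVs come from the inverse coefficient matrix of the mixed-model equations;
reliability is `r²_i = 1 − PEV_i/σ̂²_c` and the deregressed BLUP is
`BLUP_i/r²_i`, which undoes shrinkage so the stage-two response scales like
the clone's genotypic value plus noise. Records below a reliability floor
(default 0.05, overridable) are excluded — deregression divides by
reliability and blows up as PEV → σ̂²_c. Deregressed records enter stage
two unweighted; a reliability-weighting option exists but is off by
default. The clonal variance used in deregression is the one joint
stage-one estimate, not per-trial values.

Derived traits: `DMC(%) = (WA/(WA−WW))·158.3 − 142` from the air/water
weighings of the specific-gravity method (WA > WW ≥ 0 enforced; values
outside the plausible 17–38 % field amplitude are returned but logged), and
`DRY = FRY × DMC/100`.

## Marker codings and relationship matrices

Markers are oriented so the coded allele is the major one (p ≥ 0.5),
computed from non-missing calls; missing dosages are mean-imputed to `2p`
(a deliberately naive imputer — haplotype-aware imputation is out of
scope). Quality control removes markers below a 0.90 call rate or with MAF
not strictly above 0.05.

With dosage d counting major alleles, the codings are

* additive `Z`: `d − 1` ({−1,0,1}), centered by its column mean `2p − 1` by
  default. Centering only shifts the intercept, not predictions, but makes
  E(diag G) = 1 and expresses GEBVs as deviations; an uncentered switch
  reproduces the raw {−1,0,1} coding.
* classical dominance `H`: (mm, Mm, MM) → (−2p², 2pq, −2q²). This is the
  breeding-model parameterization whose columns are zero-mean under
  Hardy–Weinberg proportions, making additive and dominance variance
  components orthogonal. Printed renderings of this coding sometimes drop
  the factor 2 on the homozygote terms; without it the zero-mean property
  fails, so the canonical coefficients are used and recorded in
  `coding_note`.
* genotypic dominance `H*`: (mm, Mm, MM) → (−2pq, p²+q², −2pq).

Scalings: `G = ZZ'/2Σpᵢqᵢ`, `D = HH'/Σ(2pᵢqᵢ)²`,
`D* = H*H*'/Σ2pᵢqᵢ(1−2pᵢqᵢ)` — the canonical denominators of the two
dominance parameterizations, which make the expected diagonals ≈ 1; both
are overridable constants. For fractional (imputed) dosages the dominance
codings interpolate linearly between the adjacent genotype classes.

The RKHS kernel is `K = exp(−h·Δ/median(Δ))` with `Δ` the squared
Euclidean distances between clone rows of the {−1,0,1} coding (a
plain-distance switch exists), the median taken over off-diagonal entries
(the zero diagonal would only deflate it), and `h = 1` by default.

`condition_psd` bends numerically indefinite matrices by diagonal
inflation (`max(ε, −λ_min + ε)`, ε = 1e−6) rather than eigenvalue
truncation, preserving off-diagonal structure while guaranteeing the
Cholesky factorizations downstream.

## REML engine

One engine serves the stage-one trial model, G-BLUP (A and A+D) and RKHS:
`y = Xβ + Σ_k Z_k u_k + e`, `u_k ~ N(0, K_k σ²_k)`. All quantities are
computed from the mixed-model equations, so cost scales with the number of
equations (≤ ~1.3k here), not records. Updates are average-information
steps with three safeguards: projection onto the parameter space (clamping
at a floor of `1e−8·var(y)`), backtracking halving whenever a step would
decrease the REML log-likelihood, and an EM step (monotone by construction)
when no acceptable AI step exists. Components that sit at the floor with a
negative score are pinned and dropped from the update system — without
this, boundary components cause the classic EM crawl. Convergence: relative
component change < 1e−6 or log-likelihood change < 1e−8, maximum 200
iterations; non-convergence raises an error carrying the iteration trace.
RKHS uses the identical code path with `K` in place of `G` — one model,
two covariances.

Unphenotyped clones are carried in the random-effect covariance (records
are a selection matrix into the clone vector), so their GEBV/GEGV come out
of the same solve; GEGV for A+D models is the sum of the additive and
dominance solutions.

## Bayes B and Bayes Cπ

Single-site Gibbs samplers for `y_d = μ + Za + Hd + ε` with a point mass
at zero (exclusion probability π per effect class; the dominance design is
the classical `H`). Bayes B: per-marker scaled-inverse-χ² effect
variances, fixed π. Bayes Cπ: one variance per class, π ~ Beta posterior
under a uniform prior; its posterior mean seeds Bayes B in the pipeline
(π is re-estimated per trait/model rather than taken from any external
table). Defaults: 20 000 iterations, 4 000 burn-in, thinning 10 — the
evaluation settings of the study design this package implements; reduced
chains are used in smoke tests.

Priors: effect and residual variances are scaled-inverse-χ² with df = 5;
scales are solved so the prior means match a genomic R² of 0.5 split
equally across effect classes. In Bayes Cπ the effect-variance scale is
re-solved each iteration from the current π (so the implied prior genetic
variance is constant in π). This matters: with a fixed small scale the
chain can drift onto the degenerate ridge σ²_β → 0 where inclusion carries
no likelihood penalty and π performs an uninformed random walk; the
π-adaptive scale keeps inclusion costly on null data and π̂ correctly
approaches 1.

Genomic variances are reported on the *genetic-value* scale: at each
stored iteration the variance across clones of `Za`, `Hd` and `Za + Hd` is
recorded and posterior means of these series are returned. This
value-based accounting can exceed the phenotypic variance when effects are
uncertain, which is worth knowing when comparing against REML components.
The full-length residual-variance series is kept as the
convergence-monitored chain; `raftery_lewis` implements the two-state
Markov run-length diagnostic (dichotomize at the q-quantile, thin until
first-order by BIC, burn-in/run-length from the transition probabilities,
dependence factor `I = (M+N)/N_min`).

## Cross-validation and method comparison

One seeded plan (5 folds × 3 repetitions, balanced to ±1 clone) is served
to all six methods; every result row carries the plan hash. Predictive
ability correlates held-out predictions (GEBV for additive models, GEGV
for A+D and RKHS) against stage-one BLUPs of the validation clones — a
switch allows deregressed BLUPs instead. Bias is computed on the training
partition as `COV(pred, BLUP)/VAR(pred)` (a validation-set variant exists,
off by default). Variance components are re-estimated within each training
fold.

Method comparison fits `value ~ method` with a random rep × fold block by
maximum likelihood (statsmodels MixedLM), tests the method effect with a
likelihood-ratio χ² (df = methods − 1), and runs Tukey's HSD on the method
means using the studentized range with the model's residual variance
(the design is balanced, so marginal means equal raw means); the compact
letter display groups methods whose differences are non-significant at
α = 0.05 family-wise per statistic.

## Selection analytics

`selection_differential` takes the mean stage-one BLUP merit of the top
⌈sp·n⌉ clones by a ranking (GEBV/GEGV for genomic, BLUP itself for
phenotypic selection) minus the overall mean; BLUP merit is the common
scale that makes the GS/PS ratio meaningful. Ties at the cut break by
clone id (deterministic, logged). Efficiency is the exact quotient
`SD_GS/(SD_PS × GB/PB)` over a grid of selection proportions (5–30 %) and
cycle-length ratios (1.00 … 0.20); reports round to 2 decimals but retain
raw values. Cohen's kappa on the selected/unselected indicator vectors
measures selection coincidence; the degenerate case of two constant equal
vectors is defined as κ = 1, constant but different as κ = 0 with a
warning.

## The synthetic-data generator

The generator emulates a clonal germplasm evaluation: biallelic SNPs at
frequencies uniform on [0.05, 0.95]; panels built from founder pairs into
full-sib groups (default size 6, founders ≈ n/10 reused across families so
half-sib relationships also occur). Family structure is essential, not
cosmetic: with fully unrelated HWE clones both G and D are ≈ I plus
O(1/√m) noise and the (additive, dominance, residual) partition is barely
identifiable at panel sizes of a few hundred — relationship variance is
what REML estimates from. Marginal genotype frequencies remain
Hardy–Weinberg; `family_size=1` gives independent clones and an
inbreeding parameter F (default 0) perturbs founder heterozygosity.

Effects are simulated on the classical (orthogonal) scale: i.i.d. normal
marker coefficients for `Za` and `H_classical d`, each rescaled so the
realized variance across the panel hits its target exactly; true breeding
values, dominance deviations and genotypic values are retained.

Trait profiles calibrate to the variance-component structure of cassava
root traits: `FRY_like` (σ²_a=6.4, σ²_d=11.5, σ²_e=28.5 → h²≈0.14,
H²≈0.39), `DRY_like` (0.71, 0.79, 2.55) and `DMC_like` (1.92, 0.18, 1.92 →
h²≈0.48, H²≈0.52). These targets are expressed on the *clone-mean
(deregressed) scale*: the trial generator sets the plot residual to
σ²_e × expected plots per clone, so a clone's deregressed record is
approximately `g + N(0, σ²_e)` and stage-two heritabilities are comparable
to the targets. Each clone is planted in a fixed number of randomly chosen
trials (`incidence_rate` × trials) — trials are unbalanced in composition
while clones carry comparable information, the regime in which
deregression behaves well. Trial and replicate effect SDs default to the
genetic SD and 0.3× it. DMC plots are emitted as WA/WW weighings
back-solved from the plot value (exact inverse of the DMC formula); plot
values below ≈16.3 %, which no non-negative water weight can encode, are
clipped to 16.5 % first (a ~1 % censoring of the low tail).

What the generator does **not** emulate: linkage disequilibrium from
population history (loci are unlinked), genotype-by-environment
interaction, spatial field trends, shared non-genetic family environment,
and genotyping error. Passing recovery tests therefore demonstrates the
estimators are correct under their own assumptions, not that real cassava
data meet those assumptions.

## Calibration observed at validation scale

At the validation problem size (n = 600 clones, m = 3000 markers, 6
trials, 10 seeds), two-stage recovery medians run somewhat high of the
profile targets (ĥ² by up to ~0.07 on the yield profile, Ĥ² by ~0.02–0.06)
with per-seed spread of ±0.07 — REML variance-ratio estimates at this
panel size are noisy and the A/D partition leaks under sib-pair
collinearity (full sibs have proportional additive and dominance
relatedness). The directional cross-validation contrast is stable: the
additive-dominant model gains ~0.02–0.04 predictive ability on the
dominance-dominated profile and is indistinguishable (< 0.005) on the
additive-dominated one.

## Problem sizes used in tests and the reproduction script

Validation experiments run at n=600/m=3000 (recovery, 10 seeds;
directional CV, 3 seeds), n=200/m=1000/5k iterations (Bayes null
calibration), n=200/m=500 with 2k-iteration chains (six-method smoke run),
and exhaustive enumeration to n=12 for kappa. Unit tests use smaller
panels throughout.

## Known limitations

* Single-trait models only; no G×E covariance, no spatial adjustment, no
  single-step (pedigree + marker) evaluation.
* The mean-dosage imputer ignores linkage; with real GBS data an external
  haplotype-aware imputer should run before loading.
* The Gibbs sampler updates markers in fixed order (systematic scan);
  effective sample sizes for variance components should be checked with
  the provided diagnostic rather than assumed.
* `compare_methods` uses a normal approximation for the Tukey degrees of
  freedom rather than Satterthwaite; with 15 records per method the
  difference is immaterial.
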