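# Methods

## The model

`tilor` fits an additive threshold index logistic regression to
case-control genotype data.  Each subject carries a vector
x ∈ {0,1,2}^p of SNP codes (copies of the variant allele) and a binary
phenotype y (1 = case).  The case probability is

    P(y = 1 | x) = logistic( g1(α'x) + g2(β'x) ),

where α and β are index vectors summarizing many small per-SNP effects
into two scalar "regime indices", and each link g_k is a two-regime
affine function

    g_k(u) = b_k1 + b_k2·u   if u ≤ c_k,
             b_k3 + b_k4·u   if u >  c_k,

with an unknown threshold c_k.  The motivation is the threshold view of
polygenic disease: many risk alleles accumulate quietly until a combined
burden crosses a critical level, after which risk escalates.  The index
aggregates the alleles; the threshold link captures the qualitative
change.  Two index/link pairs are used because one pair is a special
case (set g2 ≡ 0) while three would add another p + 5 parameters with
little extra expressiveness at realistic sample sizes.

Identifiability.  The linear predictor is unchanged if an index is
rescaled (with slopes and threshold compensated) or its sign is flipped
(with the two regimes mirrored), or if the (α,g1) and (β,g2) pairs
trade labels.  The canonical representative fixes ‖α‖ = ‖β‖ = 1 with a
positive first nonzero component.  No separate global intercept is
included: the regime intercepts b_k1, b_k3 absorb it, and only the four
regime-combination sums are individually identified — which is exactly
enough, since the four sums pin all four intercepts.  The boundary point
u = c_k belongs to the lower regime; continuity at c_k is not imposed.

Two caveats the canonical form does not remove, and how the package
handles them where they matter (error summaries in the simulation study
and pooling of bootstrap replicates):

* the label symmetry (α,g1) ↔ (β,g2) survives canonicalization;
* the leading-sign rule keys on the estimate's first nonzero component,
  which in finite samples is pure noise whenever the corresponding true
  loading is ≈ 0, so the global sign of an estimated index is arbitrary
  relative to a reference.

`align_to` therefore resolves, against a reference parameter vector, the
full eight-element equivalence set (label swap × per-index sign flip
with the link mirrored) before differences are taken.

## Estimation

The log-likelihood is the Bernoulli sum Σ yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)
with probabilities clipped to [1e−12, 1−1e−12] so separation cannot
produce −∞.  The unit-norm constraints enter as a fixed quadratic
penalty λ(‖α‖−1)² + λ(‖β‖−1)² with λ = 1000 (a Lagrange-type surrogate);
the optimum is renormalized exactly afterwards, so the penalty only
needs to keep the scale pinned during the search.

The objective is non-differentiable in (α, β, c₁, c₂) — subjects jump
between regimes — so the final refinement uses the downhill simplex
(Nelder-Mead), which requires no derivatives.  The surface is also
heavily multi-modal in the index directions, and plain random multi-start
simplex runs stall in spurious basins.  Each random restart is therefore
first carried through a smoothing homotopy: the regime indicator
1{u ≤ c} is replaced by the logistic ramp σ((c−u)/h), the smoothed
penalized likelihood (which has an analytic gradient) is maximized by
L-BFGS-B, and the bandwidth is shrunk along h = 0.5 → 0.2 → 0.08 with
warm starts.  Smooth-transition surrogates are the standard device for
threshold-type regressions; here they only produce starting values — the
candidates are ranked by the exact objective and the best is polished by
repeated bounded Nelder-Mead runs (each rerun rebuilds the simplex,
which escapes stalled configurations) until the gain drops below the
simplex tolerance.  The reported optimum always comes from the exact,
unsmoothed objective.

Estimation is confined to a compact parameter box: index coordinates in
±1.5 (unit vectors live well inside), regime coefficients in ±4, and
thresholds within ±(1+√p), the attainable index range.  Compactness is
the standard regularity assumption for threshold regression, and it is
active here: the two-threshold link can isolate small quasi-separated
subgroups of subjects whose coefficients would otherwise diverge.

Defaults: 50 restarts (seeded, reproducible), 20 000 simplex iterations
per run, simplex stopping when the absolute objective spread falls below
1e−9, random starts with every coordinate uniform on ±0.5 (index blocks
normalized, thresholds placed at a random central quantile of the
start's own index values — a far-off threshold empties a regime and
strands the search), 250 L-BFGS-B iterations per bandwidth.  Reduced
settings (9 restarts, 3 000 iterations, 5 polish rounds) are used for
the replicated simulation studies; a single fit then takes a few seconds
at n = 600, p = 8.

## Bootstrap standard errors

Sampling variability comes from a parametric bootstrap (default
B = 100): responses y* are redrawn Bernoulli from the fitted
probabilities at the observed genotypes, and the model is refitted with
the original estimate (plus uniform jitter of scale 0.05) as the
starting value — the refit is local by construction, which both matches
how the original optimum was produced and keeps B refits affordable.
Replicates whose simulated phenotype is single-class are redrawn up to
ten times, then skipped with a warning; fewer than two usable replicates
is an error.  Component sds use divisor B−1 around the bootstrap mean,
after aligning each replicate to the original estimate (see above).

## Screening and evaluation

`or_screen` reduces each SNP to a 2×2 allele-count table (two alleles
per subject) and applies a two-sided Wald z-test to the log allelic odds
ratio, with the Haldane-Anscombe 0.5 correction when a cell is empty.
A SNP with a fixed allele has no allelic contrast and is reported
undefined.  Selection is at the raw per-SNP level (no multiplicity
correction): the screen is a pre-filter, not an inference.

Cross-validation is stratified by phenotype: cases and controls are each
permuted and cut into k near-equal blocks (remainders go to the last
blocks), and block j of each class forms fold j, so every fold mirrors
the study's case/control ratio.  The comparison fits the threshold index
model and a linear-logistic baseline (statsmodels GLM behind
`fit_linear_logistic`) on each training split and scores the held-out
fold: Type I error = controls called cases, Type II = cases called
controls, at the probability cut-off 0.5 (the canonical choice; in
case-majority data it makes the linear baseline over-call cases, which
is the qualitative signature to look for), plus ROC/AUC with
Mann-Whitney tie handling (scikit-learn).

## The synthetic-data generator

Genotypes are i.i.d. categorical on {0,1,2} with default probabilities
(0.25, 0.5, 0.25) — Hardy-Weinberg at allele frequency one half; the
phenotype is Bernoulli with the model probability at a specified truth.
The generator deliberately omits linkage disequilibrium, population
structure and missingness, so passing recovery tests demonstrate the
estimator's behaviour under clean conditions, not robustness to real
panel artefacts.

The packaged default truth (p = 8) was chosen for identifiability at
moderate n, on structural grounds:

* sparse, well-separated loadings with non-integer ratios
  ((1.5, 0.8, −2.2)/norm on SNPs 1-3 for α; (0.9, 1.7, −1.8, −0.7)/norm
  on SNPs 4-6, 8 for β) — integer-ratio loadings put the index on a
  coarse lattice whose gaps interval-censor the threshold;
* loading patterns summing to ≈ 0, so each index is centred near zero
  and the thresholds (0.3 and −0.2) sit in the middle of the index mass:
  both regimes are well populated and the regime intercepts are
  interpolations, not extrapolations to a u = 0 far outside the regime;
* links with a visible jump at the threshold and clearly distinct slopes
  (0.5 vs 0.8; −0.5 vs 0.6), giving case prevalence ≈ 0.60 and an oracle
  AUC ≈ 0.83 — comparable to real polygenic case-control panels.

The recovery study (`run_simulation_study`) regenerates data and refits
at each sample size (defaults 300 and 600, 100 replicates, seeds derived
from one design seed), records canonical estimates aligned to the truth,
and summarizes per-parameter absolute errors by boxplot statistics.

## Numerical choices and degenerate inputs

* Probability clipping 1e−12 before logs; likelihood is always finite.
* Boundary u = c belongs to the lower regime everywhere.
* Simplex: scipy Nelder-Mead with adaptive coefficients, absolute
  function tolerance = the configured simplex tolerance, xatol 1e−8.
* Monomorphic SNPs, single-class phenotypes, zero-norm index vectors,
  non-finite link arguments, dimension mismatches and invalid genotype
  codes all raise typed errors rather than propagating NaNs.
* All randomness flows through seeded numpy Generators; identical seeds
  give bit-identical fits, fold assignments and simulations.

## Known limitations

* The optimizer is a global-search heuristic on a multi-modal surface;
  with few restarts on hard data it can return a local optimum (the
  `converged` flag and restart objectives help diagnose this).
* Regime coefficients are reported on the raw scale; when a regime
  covers few subjects its intercept/slope pair is strongly negatively
  correlated and individually imprecise even when the regime's fitted
  line is stable.
* The coefficient bound (±4) is a modelling assumption; data whose true
  effects exceed it will show estimates at the boundary.
* Threshold estimates inherit interval identification from the discrete
  genotype support: the likelihood is flat between consecutive observed
  index values.
* In cross-validation at study-sized samples (a few hundred training
  subjects) the model's extra flexibility costs variance: on truths whose
  nonlinearity is only moderate, the linear-logistic baseline can match
  or beat it out of sample, and the threshold model's advantage emerges
  only when the links are strongly non-monotone or the training set is
  larger.
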