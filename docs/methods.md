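# Methods

## Model and estimation

The engine is generalized least squares with a phylogenetic error
structure. A rooted phylogeny with branch lengths defines the Brownian
covariance matrix **C**: entry *(i, j)* is the root-to-MRCA shared path
length, the diagonal the root-to-tip depths. Pagel's λ rescales the
off-diagonal entries only, `V(λ) = λC + (1−λ)diag(C)`, interpolating
between independent tips (λ=0) and full Brownian covariance (λ=1). On a
non-ultrametric tree λ=0 leaves unequal diagonal depths, so the classical
"λ=0 equals OLS" identity holds exactly only for ultrametric trees; the
equivalence tests use ultrametric (Yule) trees for this reason.

The profiled log-likelihood at fixed λ sets β to its GLS estimate and σ² to
RSS/n:

```
log L(λ) = −½ [ n log(2π σ̂²) + n + log|V(λ)| ]
```

computed through a Cholesky factor of V(λ); no explicit inverse is formed.
Estimation is full ML, not REML, so log-likelihoods and AICc are comparable
across models with different fixed effects. Coefficient standard errors use
the unbiased whitened-space variance RSS/(n−p), the classical GLS
convention.

λ maximization: a 21-point grid on [0, 1] seeds a bounded scalar search
(tolerance 1e-6) bracketed by the best grid point's neighbours; both
boundaries are checked explicitly because the profile is often maximized at
0 or 1 and can be multimodal near the boundaries. Boundary hypothesis tests
(λ=0: no signal; λ=1: Brownian) use P(χ²₁ ≥ 2Δlogℓ); the 50:50
boundary-mixture correction, which halves that p-value, is available behind
a flag but off by default to match long-standing practice in comparative
packages.

Degrees of freedom for AICc count intercept + slopes + residual variance,
plus one for λ only when λ is estimated (`lambda_mode="ml"`); a fixed λ is
not a fitted parameter.

R² is reported in the whitened (GLS-transformed) space, with the total sum
of squares taken around the GLS intercept-only fit under the same λ. This
keeps R² in [0, 1] under any admissible V(λ).

Numerical guards: a Cholesky failure, or a condition number above 1e12
(screened cheaply via the Cholesky diagonal ratio), raises a singularity
error naming the most similar pair of taxa — typically a zero-length cherry
from a consensus tree — rather than silently regularizing, because jitter
would change likelihoods. Perfectly collinear designs raise a
rank-deficiency error naming the offending columns.

## Trait preparation

Portmann's intra-cerebral indices times the "chiffre basal" (the predicted
brain-stem mass in grams of a galliform bird of equal body mass) give
absolute component masses; whole brain is the sum of the four components.
All analysis variables are log₁₀-transformed; non-positive values abort
with the species and column named. Organ sizes (four components, whole
brain, eye) enter models only as residuals from their own independent PGLS
regression (λ by ML) on log *specimen* body mass — the mass of the
individuals whose brains were measured, not the species mean — returned on
the observation scale since they act as ordinary predictor columns
downstream. A species missing an organ measurement is dropped from that
organ's allometric fit (logged in the metadata) and gets a NaN residual;
model selection then uses complete cases across all candidate predictors so
every candidate model shares the same n, which AICc comparison requires.

## Model selection and averaging

All subsets of the seven free predictors plus the whole-brain subsets
(whole brain never with a component) give 136 candidates, including the
intercept-only model, which participates in weight normalization. Each
candidate re-estimates its own residual λ in ML mode; the constrained
analysis fixes λ=1 in every candidate. Ranking is by AICc with ties broken
by fewer predictors then lexicographic order.

Averaging is *conditional* (over models containing the predictor) by
default, with the zero-substituted full-model average behind a flag; the
unconditional standard error folds between-model spread into the
within-model sampling variance, and intervals use the normal 1.96
multiplier (a t-quantile option exists). The choice matters only in the
third decimal for strongly weighted predictors but substantially for weak
ones, which is why both variants are exposed.

Cross-phylogeny pooling is the arithmetic mean of predictor weights,
averaged coefficients and CI bounds over trees, at full precision. CI
bounds are averaged directly rather than re-derived from pooled variances,
matching how a single pooled interval per predictor is conventionally
presented. Each tree's analysis is fully independent — no λ or residual
sharing.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not any real dataset. Trees are Yule (pure-birth, rate 1.0) with the clock
run past the final speciation by the Exp(n·rate) waiting time to the next
event, so trees are ultrametric with no zero-length terminal cherry.
Traits are drawn directly from the multivariate normal implied by the
λ-transformed covariance — exact by construction, simpler than edge-wise
Brownian increments, and exactly the model the estimator assumes. Root
state is 0 on the log₁₀ scale throughout; location affects no estimator
used.

Default study conditions (all log₁₀ scale): 41 species; starting distance
mean 1.4 (≈25 m), λ=0.8, rate 0.02; body mass mean 2.0 (100 g), λ=1, rate
0.1; specimen mass = species mass + N(0, 0.02²); organ allometries with
slopes 0.57–0.60 and λ≈0.9 deviations of SD 0.05–0.07, giving organ–mass
correlations above 0.8; response = −0.35 + 0.6·SD + 0.25·mass −
0.3·(cerebellum deviation) + N(0, 0.1²) i.i.d. noise (residual λ = 0, the
error structure the ML analysis is expected to find). The five-phylogeny
fixture perturbs one base tree: log-normal branch jitter (SD 0.15), equal
branch lengths, a consensus-like copy with the five shortest internal
branches collapsed to zero and re-resolved, and a 2× rescaling.

What the generator does **not** emulate: measurement error, the FID ≤
starting-distance truncation, non-Gaussian tails, missing data patterns,
and real cross-study heterogeneity in eye-volume units. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness of the biological conclusions to those features.

## Known limitations and measured behaviour

The ML estimator of λ is biased toward 0 at low-to-mid true λ in samples of
this size (boundary pile-up at λ̂=0): at n=128 the mean recovered λ at true
λ=0.25 is ≈0.19, while true 0, 0.5, 0.75 and 1 are recovered within ±0.05
and the means are monotone in the truth. This is a property of the
estimator itself — per-replicate estimates agree with an independent
implementation to ~1e-4 — and is visible in the recovery numbers the
acceptance script reports.

Problem sizes used by the shipped experiments, chosen to make Monte-Carlo
error small relative to the effects examined: λ recovery uses a 128-tip
tree with 200 replicates per true λ in the test suite and 100 in the
acceptance script; the end-to-end ranking check runs the full 136-model ×
5-phylogeny pipeline on 20 seeded 41-species datasets; smaller unit
property checks use 6–64 tips.

Out of scope by design: other branch-length transformations (κ, δ, OU),
REML, measurement-error models, ultrametricization of input trees (trees
are used as supplied), consensus-tree construction, and Bayesian averaging
over tree posteriors — only fixed alternative phylogenies are consumed.
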