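# Methods

## The estimation problem

A rare-disease missense variant is typically known from a handful of
heterozygous carriers: a few case reports contribute affected carriers, a
population database (gnomAD-style, filtered to allele frequency < 0.01%,
the default `af_threshold = 1e-4`) contributes carriers presumed
unaffected.  The observed penetrance αᵢ/(αᵢ+βᵢ) of such a variant is a
binomial proportion from a tiny sample and is usually 0 or 1.  The package
treats penetrance as a latent probability shared through a hierarchical
beta-binomial model and reports calibrated posterior estimates with
uncertainty, rather than classifications.

Assumptions worth stating plainly:

* population-database carriers of rare variants are unaffected — accepted
  as an approximation (for a disease with ~1:10,000 incidence the
  contamination is negligible);
* carriers are independent; compound heterozygosity and family structure
  are outside the model;
* all counts refer to one fixed transcript's residue numbering.

## Evidence weights

Every variant gets weight w = 1 − 1/(0.01 + n), n = total carriers,
clamped to [0, 1].  A singleton has w ≈ 0.0099, n = 100 gives w ≈ 0.990.
The printed constant 0.01 makes the literal formula negative at n = 0;
zero-count variants are excluded from fitting (they only ever receive
prospective priors), and the clamp records the view that a weight is a
confidence mass.  A gentler ramp 1 − 1/(1 + 0.01 n) is available as
`form="soft"` for sensitivity analyses.  Weights are normalized to sum to
one inside every average; without normalization a "weighted mean" of
probabilities is not itself a probability.

## Empirical prior

The shared prior is Beta(α₀, β₀) with mean fixed to the weight-normalized
average of observed penetrance.  The concentration ν = α₀ + β₀ must be
identified from the *spread* of the ensemble, not from per-variant fit:
any criterion that scores the conjugate posterior against the same
variant's observed penetrance is minimized as ν → 0 (the residual is
ν(m − pᵢ)/(nᵢ + ν), monotone in ν), so it cannot calibrate shrinkage.
The default therefore maximizes the weighted beta-binomial marginal
log-likelihood over log ν with the mean held fixed — the standard
empirical-Bayes route, which recovers the generative concentration within
a factor of ~1.2 at the test scale (2,000 variants).  The degenerate
squared-error criteria are retained as `method="mse_loo"` /
`"mse_insample"` for transparency; they pin ν at the lower search bound
(0.1) and are not recommended.  Optimization is bounded scalar
minimization over log ν ∈ [log 0.1, log 10⁴] (tolerance 1e-6), with a
log-spaced grid fallback.

## EM covariate calibration

Covariates: REVEL and AlphaMissense scores in [0, 1]; ClinVar encoded
1 for P/LP and 0 for VUS/B-LB (VUS carriers are treated as unaffected, as
in clinical practice), missing when unclassified; and the structural
disease density below.  All are standardized by weighted mean/SD;
missing values are weighted-mean-imputed with a paired missingness
indicator; constant or all-missing columns are dropped with a warning.

The fixed-point loop: responses start at the empirical posteriors; each
iteration fits weighted least squares of logit(response) (clipped to
[1e-4, 1−1e-4]) on the covariates, maps fitted means p̂ᵢ to priors
(p̂ᵢν, (1−p̂ᵢ)ν), and recomputes responses as conjugate posteriors under
those priors.  It stops when max |Δp̂ᵢ| < 1e-6 (default) or after 100
iterations.  The concentration ν is carried unchanged from the empirical
prior: the covariates re-calibrate the prior *mean* per variant while the
ensemble calibrates uncertainty once.  The linear-on-logit family was
chosen for closed-form stability inside a fixed-point loop; it converges
in 15–30 iterations on all test fixtures, and the max-change trajectory is
monitored (the scheme is a fixed point, not a guaranteed-monotone
optimization, so the trajectory is exposed on the fitted model).

Evaluation-time fits are leave-one-out: the held-out variant's counts
never reach its fold's prior or regression, and its density covariate is
computed with its own counts removed.  Prospective (all-data) fits are
used for final estimates.

## Structural disease density

density(r) = Σ_v w_v α_v k(d(r, res(v))) / Σ_v w_v n_v k(d(r, res(v))),
with k a uniform cutoff at radius 15 Å on Cα–Cα distances (an exponential
kernel is available; the radius and kernel are configuration).  The value
is a weighted affected fraction, hence in [0, 1]; a residue with no
carrier mass in its neighborhood has undefined density.  Density is
computed on a single protomer chain; inter-protomer neighborhoods of
multimeric channels are not modelled (a known limitation).  Unresolved
residues yield missing densities, which the regression handles through
imputation + indicator.  Exports write per-residue values into PDB
B-factors (sentinel −1.0 for unmapped residues) for rendering.

## Hot-spot scan

Windows of 100 residues qualify when they hold ≥ 4 variants (strictly
"more than 3") and the mean penetrance over *variant-bearing* residues
strictly exceeds 0.4.  Averaging over variant-bearing residues (rather
than diluting by empty positions) is the reading under which a tight
cluster of ~8 high-penetrance variants inside a window can qualify; the
diluted alternative is a flag.  Qualifying windows that overlap or touch
are merged and each merged segment is trimmed to its outermost
variant-bearing residues.  Note the *number* of segments is not monotone
in the thresholds — a stricter threshold can split one merged run in two —
but the covered residue set shrinks monotonically, and that is the
invariant the tests assert.

## Evaluation

* Brier score: mean squared error of probabilistic forecasts; outcomes are
  empirical posteriors for forecast evaluation, observed penetrance for
  in-sample calibration checks.
* Weighted Spearman: weighted Pearson correlation of mid-ranks (average
  ranks on ties).
* ROC AUC by the Mann–Whitney concordance formulation (ties ½);
  PR AUC by the interpolation-free step estimator.  Confidence intervals
  are percentile bootstrap, 2,000 resamples stratified by class, seeded.
* Binary outcome: a variant is "affected" when it has ≥ 1 affected
  carrier; a posterior-threshold alternative is available since curated
  datasets differ in how they define per-variant status.
* Metrics can be stratified by allele frequency (< 1% vs all).
* K-fold CV partitions *sorted keys* by a seeded permutation, so the folds
  and pooled metrics are invariant to input row order.

## Synthetic study conditions

The generator emulates what curated rare-disease tables actually look
like: true penetrance logit(pᵢ) = logit(baseᵢ) + Σ effect·xᵢ + cluster
boost, baseᵢ ~ Beta(1, 60) (mean ≈ 1.6%, heavy zero-inflation); 60%
singleton carriers, non-singleton totals 1 + Poisson(19); counts binomial;
covariates observed through unit-variance Gaussian noise and squashed to
score-like [0, 1] ranges; ClinVar labels assigned for half the variants by
thresholding a noisy copy of true penetrance.  Variant keys are unique
(position × substitution sampled without replacement).  By default three
clusters at L/5, L/2, 4L/5 add +4.2 logit at their centers (Gaussian decay,
spread 10), lifting baseline variants to hot-spot-level (~0.5) penetrance;
the hot-spot demonstration additionally concentrates 60% of variant
*positions* at the clusters, because detection requires both elevated
penetrance and locally concentrated reports — as in real curated data.
The toy structure is a persistent self-avoiding 3D chain (3.8 Å steps,
≥ 4 Å non-consecutive clearance), sized so density neighborhoods are
non-trivial.

What passing on synthetic data does *not* show: robustness to literature
ascertainment bias beyond singleton inflation, transcript/numbering
mismatches, curation errors, or the realism of any particular covariate's
error structure.  Real-data metric magnitudes (Spearman, Brier, AUC)
depend on the curated dataset and are not reproduced by simulation; the
tests establish correctness of the arithmetic and recoverability of known
generative parameters, not clinical performance.

## Problem sizes and numerical choices

Recovery studies use 2,000 variants (10–20 seeds), matching the scale the
model targets while keeping the full suite in seconds.  The hot-spot study
uses 250 variants on a 500-residue protein (sparser, clustered landscape).
Degenerate inputs: zero-carrier variants are excluded at finalization;
all-zero weights raise; responses are clipped before the logit; collinear
or constant covariates are dropped, not inverted through; beta quantiles
come from the regularized incomplete beta inverse (scipy).
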