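# Methods

## Model and estimation

Survival follows the Cox proportional-hazards model: the hazard of a patient
with feature vector x is h(t|x) = h₀(t)·exp(xᵀβ).  All fitting works through
the Breslow partial log-likelihood; tied event times are handled with the
Breslow approximation throughout (partial likelihood, score statistics, and
the Cox–Oakes baseline-hazard estimator all share the same risk-set
formulation, so one tie convention keeps them mutually consistent).  Efron's
correction is not implemented.

Penalized fits follow the glmnet convention, maximizing
(1/n)·pll(β) − λ(α‖β‖₁ + (1−α)/2·‖β‖₂²).  Features are standardized to
mean 0 / variance 1 on the training data before fitting — the penalties are
scale-sensitive — and coefficients are reported on the original scale.
Elastic-net/lasso problems (α > 0) are solved by the coordinate-descent path
solver of scikit-survival; ridge and unpenalized problems by a damped
Newton–Raphson solver with step halving.  Lasso coefficients below 1e-9 in
standardized magnitude are snapped to exact zero so that the support of a
fit is well-defined.  The λ grid is 100 log-spaced points from λ_max (the
smallest penalty that zeroes the model) down to 0.01·λ_max; cross-validation
folds (default 5) are stratified by the event indicator and scored by the
held-out partial likelihood, with ties broken toward the larger penalty.

## Preconditioned lasso

The preconditioning stage ranks features by the absolute univariate Cox
score statistic |U/√V| evaluated at β = 0 — the reading of "correlation to
survival" used by the supervised-principal-components literature.  The score
threshold is searched over 20 quantiles of the score distribution between
the 50th and 99th percentiles, jointly with the number of components
m ∈ {1, 2, 3} ("the first few"), by stratified CV on held-out concordance;
ties prefer the larger threshold, then the smaller m.  Principal components
are computed by SVD of the centered, scaled selected submatrix with a
deterministic sign convention (largest-magnitude loading positive); the
component regression carries a 1e-6 ridge so near-separable low-dimensional
fits stay bounded.  The pseudo-outcome ŷ is the SPC linear predictor on the
full training set.

The lasso step regresses ŷ on *all* features of the (prefiltered) universe,
not only the SPC-selected ones.  Its penalty cannot be tuned by
cross-validating the squared error to ŷ: since ŷ is an exact linear function
of the selected features, that error falls monotonically all the way to the
interpolating fit.  Nor can a pseudo-outcome computed on the full training
set be scored against "held-out" patients — the supervised preconditioner
has already seen their outcomes, which makes pure noise look predictive
(observed held-out concordance ≈ 0.73 on null data).  The penalty is
therefore chosen by *nested* CV: inside each fold the preconditioner
(feature scores, the selection cut at the quantile chosen by the outer
tuning, components, component regression) is refitted on the fold's
training part only, the LARS lasso path is fitted to the fold-local ŷ, and
each penalty — compared on the relative λ/λ_max scale so folds are
commensurable — is scored by concordance on the truly held-out patients.
The sparsest penalty within one standard error of the best mean concordance
wins (the usual parsimony rule).  Under this rule pure-noise data yield
(near-)empty models while strong planted signals are recovered.

## Robust selection

The inner loop draws T_in (default 100) random sub-train/tuning splits of a
train set at the 63.2% : 36.8% ratio, the large-n effective fraction of
distinct samples in a bootstrap resample (1 − (1 − 1/n)ⁿ → 1 − 1/e).  Splits
whose sub-train part carries no event are redrawn (up to 100 times) rather
than stratified, staying closest to plain random subsampling while remaining
well-defined.  Base-learner hyperparameters are retuned on every sub-train
set.  The T_in coefficient vectors are averaged arithmetically; exact
cancellations are kept as zeros.  Shrinkage scans K = 50 evenly spaced
thresholds between the smallest and largest nonzero aggregated magnitude,
zeroes coefficients below each threshold, and keeps the threshold whose
truncated linear predictor attains the best mean concordance over the tuning
sets, ties toward the sparser model.  Surviving coefficients keep their
averaged values — the aggregate is thresholded, not refitted.

SD prefiltering drops the features whose training-set standard deviation
lies below a configured percentile — exactly floor(p·q/100) features, ties
at the cutoff keeping the lower index; SDs are computed within each train
set, never globally.  The default percentile is 0 (off): the synthetic
cohorts draw every feature with equal variance, so variance filtering
carries no signal there.  On real microarray universes 90–99 are the
typical settings, and the retention arithmetic reproduces the
2285 / 2848 / 2050 feature counts of the 228476 / 28476 / 20492-feature
platforms at q = 99 / 90 / 90.  For comparability the same prefilter
configuration is applied to the standalone PL and L methods as to the RS
variants.

## Outer evaluation

T_out (default 100) random 63.2% train/test splits of the cohort are drawn
once and reused verbatim by every method, so cross-method contrasts are
paired; the one-sided method comparison is implemented as a paired t-test on
per-split differences (the pairing over shared splits is what the design
supports).  A feature's selection probability is its exact appearance
fraction among the T_out fitted supports — counted after RS shrinkage,
before any extra top-G truncation.  The robust signature at baseline
probability π is the set {k : π̂_k ≥ π}, ordered by decreasing π̂, then
decreasing |mean coefficient|, then feature id; π is a user-supplied number
(anchoring it to a reference covariate's own probability is left to the
caller).  Extra shrinkage truncates a fitted vector to its G
largest-magnitude features (ranks 1..G, ties toward the lower index); trials
whose support is smaller than G are flagged and excluded from size-G
stability summaries.  The Dev and Cor baselines ridge-fit the top-100
SD-ranked and |c − 0.5|-ranked features respectively (the list size is
configurable); Cli fits an unpenalized Cox model on one-hot-encoded clinical
covariates via lifelines.

## Metrics

The concordance index enumerates all patient pairs; a pair is usable unless
both patients have events at the same time or the shorter observed time is
censored (a censored patient tied in time with an event patient is taken to
outlive them; pairs of censored patients are never usable).  The index is
the fraction of concordant pairs among concordant-or-disconcordant ones:
prediction-tied pairs drop out of both counts, the convention under which a
binary predictor's concordance equals its AUC.  Univariate feature
concordances treat columns with no untied usable pair (constant features)
as chance level, 0.5.

Kuncheva's index chance-corrects pairwise overlap of equal-size signatures:
(|A∩B| − k²/p)/(k − k²/p).  The Canberra rank distance compares top-k lists
with unselected features at rank k+1, normalized by the expected distance of
two independent uniformly random top-k lists over p features — estimated
once per (k, p) by Monte Carlo with a fixed internal seed and 10,000 draws,
so chance-level rank agreement scores ≈ 1 (the normalizer also admits a
closed form by linearity of expectation, which the test suite uses as an
independent check).  The rank-penalized Kuncheva index is
max(Kuncheva, 0) / Canberra: 0 at or below chance-level overlap, +∞ for
identical rankings.  The exact algebra of this composite is a documented
convention of this package rather than a canonical formula.

## Synthetic cohorts

The generator plants a sparse linear Cox signal: event times
T = −log(U)/(λ₀·exp(xᵀβ*)) with an exponential baseline (closed-form,
exactly proportional-hazards), features drawn as block-correlated Gaussians
(independent blocks of 10, exchangeable within-block correlation 0.2 by
default — enough to exercise correlated-feature behavior without collapsing
the signal), and censoring times exponential with a rate calibrated by
bisection on E[c/(c + θᵢ)] so the expected censored fraction hits the
target; censoring is independent of covariates (random censoring).  Default
conditions — n = 150, p = 300, s = 5 true features of magnitude 1.5 with
alternating signs spread across distinct blocks, 30% censoring — define the
study condition used by the recovery experiments; a target of 0 disables
censoring.  What the generator does *not* emulate: probe-level measurement
noise, platform/batch effects, non-proportional hazards, informative
censoring, or heavy-tailed expression distributions — passing recovery tests
demonstrate correctness of the machinery under the stated model, not
performance on real microarray data.

## Problem sizes and determinism

The bundled experiments run the recovery study at T_out = T_in = 20 (the
production default of 100/100 simply sharpens the same estimates), n = 150,
p = 300; at that size the full study completes in a few minutes on one CPU.
Every random draw — cohort generation, splits, CV folds — derives from the
run's single seed; per-trial and per-subsample seeds are spawned
deterministically from it, so reruns are bit-identical and the trial count
can be extended without perturbing earlier trials.

## Known limitations

- Breslow ties only; no time-varying covariates or competing risks.
- The concordance index is Harrell's; no IPCW correction, so heavy
  censoring biases it toward optimism.
- The preconditioned lasso's selection consistency arguments motivate but do
  not guarantee behavior at these sample sizes.
- `run_evaluation` holds the cohort in memory and runs trials serially; the
   outer loop is embarrassingly parallel but not parallelized here.
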