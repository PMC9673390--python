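# Methods

## The model

The outcome is case-control status (SMI = 1). The risk model is an ordinary
logistic regression on up to eleven predictors: eight photopic cone ERG
parameters — a- and b-wave amplitude (µV) and latency (ms), each measured at
a fixed 7.5 cd·s/m² flash and at Vmax — plus age (years), sex (male = 1) and
pupil size (mm). Fitting is maximum likelihood via IRLS (statsmodels GLM,
binomial family), deviance-change tolerance 1e-8, at most 100 iterations.
Perfect or quasi-perfect separation is detected from IRLS warnings and from
diverging standardized coefficients (|β|·SD(x) > 15) and is reported as a
non-converged model with a diagnostic; a rank-deficient design raises an
error naming the collinear terms. Predicted probabilities are clipped to
[1e-10, 1 − 1e-10] so likelihood-based metrics stay finite.

Term selection is bidirectional AIC stepwise from the full model: at each
step all single-term deletions and re-additions (within the full scope) are
scored, the lowest-AIC move is taken while it improves, and ties break
toward the earliest candidate in input order. Starting from the full model
guarantees the selected AIC never exceeds the full model's, and the result
is a local AIC optimum. AIC is recomputed as −2ℓ + 2k (k counting the
intercept), so the identity holds exactly for every reported model.

## Splitting

The split is stratified by group with a per-group training share of
round(ratio·n) (half-up). At the default 80:20 this maps 301 cases / 200
controls to 241/160 training and 60/40 testing — the partition the analysis
is designed around. Stratification is adopted because those group-wise
counts are exactly 80% per group.

## Validation metrics

* **Brier score** — mean of (p − y)²; the constant-prevalence predictor
  scores exactly π(1 − π).
* **Nagelkerke R²** — Cox–Snell R² = 1 − exp(2(L₀ − L₁)/n), rescaled by its
  maximum 1 − exp(2L₀/n). For LOOCV and external predictions, where no
  refit likelihood pair exists, L₁ is scored directly from the out-of-fold
  probabilities and L₀ from the observed prevalence; the statistic is
  floored at 0.
* **Hosmer–Lemeshow** — subjects are binned into risk deciles (default 10;
  ties share a bin, so bins may be unequal); the statistic sums
  (O − E)²/E over events and non-events per bin; df = bins − 2 and the
  p-value comes from the χ² upper tail. Bins with vanishing expected events
  or non-events are merged with a neighbour rather than divided by zero.
  The bins − 2 reference is the correct null for probabilities fitted on
  the same data; type-I error at the nominal 5% is verified by simulation
  in the acceptance suite.
* **LOOCV** — n refits with the selected model's fixed term set; each
  subject's probability is out-of-fold. Any non-convergent fold aborts the
  run loudly.
* **ROC/AUC** — empirical curve (scikit-learn), AUC as the tie-corrected
  Mann–Whitney statistic, 95% CI from the DeLong midrank variance
  estimator (clipped to [0, 1]).
* **Accuracy** — the half-open rule p ≥ t ⇒ positive is used identically
  everywhere (ROC, accuracy, net benefit, TG-ROC profiles), avoiding
  boundary disagreements between stages.

## Decision curve analysis

Net benefit at threshold probability pt weighs false positives by the odds
pt/(1 − pt). The grid is 0.01…0.99 in steps of 0.01 (configurable).
Treat-none is identically 0; treat-all equals π − (1 − π)·pt/(1 − pt) and
crosses 0 at pt = π. The superiority range is the widest contiguous grid
interval on which the model's curve is ≥ the better comparator, requiring
strict superiority at at least one point so that equality plateaus neither
count alone nor fragment a range. The pipeline computes the curve on the
test partition by default (`dca_on="train"` is available) and records which
was used.

## Trichotomization

The uncertain zone is the closed interval [t_low, t_high]: certain-positive
means score > t_high, certain-negative score < t_low. With t_low = t_high
and no score exactly on the boundary this collapses to the dichotomous
confusion matrix; scores exactly at a collapsed boundary remain uncertain.
Certain-zone Se/Sp/accuracy return NaN when a denominator is empty (e.g. a
tiny test set whose cases are all uncertain).

**TG-ROC.** Sensitivity and specificity are stepped against the threshold;
t_low is the largest candidate with Se ≥ θ and t_high the smallest with
Sp ≥ θ (θ = 0.90 default). Candidates are the observed scores plus midpoints
of consecutive scores, with sentinels beyond the extremes; Se/Sp are not
interpolated (conservative step rule). When the groups are so separated
that t_low > t_high, both cutoffs collapse to the Se = Sp crossing and the
uncertain zone is empty.

**Uncertain interval.** The intersection x* of the case and control score
densities is estimated by Gaussian KDE with Silverman bandwidth; among
multiple crossings the one between the group medians (closest to their
midpoint) is preferred, and with no crossing at all the pooled median is
used. The search then enumerates every candidate pair t_low ≤ x* ≤ t_high
from the score-plus-midpoint grid, computes Se and Sp restricted to the
subjects inside the closed interval (dichotomized at x*), and among pairs
with both ≤ 0.55 keeps the pair enclosing the most subjects (ties: narrower
interval, then lower t_low). Maximizing the enclosed count captures the
"scores better not used for diagnosis" maximally; the selection rule and
bound are configurable. The search is exact (vectorized exhaustive
enumeration), verified against an independent brute force in the tests.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not any real
patients. Group sizes (301/200), age moments (40.1 (9.9) vs 39.35 (10.3)
years), male proportions (60.5% / 62%) and pupil size (≈3.8 (1.1) mm) follow
the published descriptives. The eight ERG features are multivariate normal
with a single common pairwise correlation (default 0.4 — a- and b-wave
parameters of one eye are correlated in practice; the true covariance is
unknown, so this is a modelling choice exposed in the config). Control
means/SDs are synthetic defaults at plausible photopic cone-ERG magnitudes
(e.g. a-wave ≈ 25 (6) µV, b-wave latency ≈ 30 (1.5) ms); they are not
measurements. Case means are shifted by standardized effect sizes with the
signs seen in practice (reduced a-/b-wave amplitudes, prolonged b-wave
latencies), scaled analytically so the population Mahalanobis distance Δ
gives an optimal AUC = Φ(Δ/√2) ≈ 0.85, matching the discrimination regime
the published model operates in. Age, sex and pupil carry essentially no
group signal, mirroring the reported null descriptive comparisons.

A second mode draws features from the control distribution for everyone and
samples the label from a known logistic model; it exists for
parameter-recovery checks (the fitted coefficients can be compared with the
truth). In this mode `n_case` is the total sample size and the achieved
case count is random.

What passing tests on these cohorts do **not** show: robustness to missing
data (complete data is an input contract), non-Gaussian or heteroscedastic
ERG distributions, measurement drift, medication effects, or real
feature-covariance structure. Results on synthetic cohorts are statements
about the pipeline's correctness, not about ERG's clinical performance.

## Problem sizes and determinism

The acceptance run uses the reference cohort (n = 501) including full LOOCV
(401 refits, a few seconds). Monte-Carlo checks use 20 seeds at n = 5000
for coefficient recovery, 20 seeds at n = 2000 for stepwise retention, and
500 replicates at n = 400 for the Hosmer–Lemeshow type-I error — sizes at
which the asymptotics under test are expected to hold while the whole suite
stays fast. One master seed feeds per-stage substreams (simulation, split),
so changing one stage's settings does not shift another's randomness;
every reported number is reproducible from config + seed.

## Known limitations

* The TG-ROC certain-zone sensitivity is scored on a finite test set, so
  the preselected θ = 0.90 is met on the training profile's step function,
  not guaranteed in expectation on new data.
* DeLong CIs are Wald-type and can be degenerate at AUC = 1 on small
  samples; a bootstrap alternative is not currently wired in.
* The KDE intersection is bandwidth-dependent; with identical group
  distributions the crossing is noise-driven, and callers can pin
  `intersection=` explicitly.
* Nagelkerke R² from out-of-fold predictions is floored at zero, so it
  cannot signal worse-than-null external performance; the Brier score can.
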