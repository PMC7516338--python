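# Methods notes

This note records the modelling assumptions, defaults, and numerical
choices behind `retroeval`, and what the synthetic-data validation does and
does not establish.

## The evaluation-model family

All models map a sequence of moment utilities x_1 … x_t (picture preference
ratings on the 1–9 scale) to a total utility y(t) that is compared to the
participant's remembered utility. Model quality is the Pearson correlation
ρ = corr(y_model, y). Pearson correlation is the single optimization
criterion because moment and sequence ratings live on a priori different
scales: for any model written as f(x; θ), minimizing the MSE of the
affinely rescaled prediction a·f + b over (a, b, θ) equals maximizing |ρ|
over θ, via the identity MSE/s_y² = 1 − ρ² at the closed-form (a, b).
Every linear-model fit records its gap in this identity as a diagnostic;
the test suite requires it below 1e-10. Spearman and Kendall correlations
are computed as robustness checks only, never optimized.

Model-specific choices:

- **Linear weight fits** (order / relative-preference indexing) use OLS
  with an intercept; raw weights are divided by their sum to sum to one
  (a positive rescale that leaves ρ unchanged when the sum is positive).
  A near-zero weight sum (|Σw| < 1e-6) raises an error instead of
  producing huge weights. Rank ties in relative indexing are stable:
  the earlier position gets the lower rank.
- **λ-mixture of order and rank weights** reuses the two separately
  fitted deviation vectors ("partial optimization") because the
  position- and rank-indexed regressors are strongly collinear; λ is a
  0.01-step grid search over [0, 1], ties to the smaller λ.
- **Absolute-preference weights** w_i = 1/n + f(x_i) make the model
  nonlinear in x but linear in the weight parameters, so the
  correlation-optimal weights come from OLS on per-bin (or per-knot)
  aggregated regressors; the test suite verifies this closed form is not
  beaten by a direct nonlinear search. For fixed-length trials the family
  is over-parameterized (the sequence mean lies in the span of the bin
  sums); the reported weights are the canonical representative whose
  deviations sum to zero.
- **Preference weight function**: 5 free values at utilities
  {1, 3, 5, 7, 9} — evenly spaced over the 17 half-point rating levels —
  linearly interpolated. The knot placement is a package choice; nothing
  in the model requires these particular anchors.

## Window selection

For each candidate window k, the estimator (windowed average, peak-end, or
preference-dependent) is applied to every trial of length ≥ k; shorter
trials are unusable (the preference-dependent variant refits its 5-knot
regression per k and needs the sample, and the other estimators skip the
same trials for comparability). Candidates with fewer than `min_samples`
(default 30) usable trials are skipped — with 50 continued-task queries
this caps the tested k near 49. The candidate's score is the mean of its
leave-one-trial-out jackknife correlations ("remove one element" applied
at the trial level); candidates below the two-sided critical r for
p < 0.05 at the available n are discarded. The winner is the candidate
whose jackknife correlations beat the largest number of other candidates
in a one-sided paired t-test at α = 0.05, ties to the smallest k
(parsimony). Whether the per-k significance test should be one- or
two-sided is genuinely open; the filter uses the two-sided critical value
and the pairwise comparison a one-sided test, both at 0.05.

## Discounting optimizer

SD and PD fits minimize SSE(y, a·model + b) where (a, b) are closed-form
by simple regression at every step and the free rates move by gradient
descent with analytic gradients. Steps are projected into [0, 1] — the
rates are forgetting probabilities (End at 0, Average at 1), so the bound
is part of the model, and the fit records a diagnostic if the closed-form
scale a would have gone negative (a > 0 is enforced conceptually; on all
realistic data the unconstrained optimum already has a > 0). The step size
starts at 1e-4 and adapts multiplicatively (×1.1 on an accepted step, ×0.5
on a rejected one), so the accepted-step SSE trace is non-increasing by
construction; convergence is a relative SSE improvement below 1e-8
(default) or 50,000 iterations; 200 consecutive rejections raise an
optimizer error carrying the trace. PD initializes its five knots at the
fitted SD rate, which makes the nesting property (ρ_PD ≥ ρ_SD up to
tolerance) a consequence of monotone descent rather than luck. With the
convention 0⁰ = 1, r = 0 reproduces the End estimator exactly.

The recurrent reformulation of the PD sum (one leaky accumulator per
distinct preference level, h_{i,t} = r_i h_{i,t−1} + g_{i,t},
y_t = Σ x_i h_{i,t}) is implemented purely as an independent evaluation
path; the suite requires agreement with the direct sum to 1e-10. It is
never trained as a network.

## Combined WP-PD model

The mixture y = λ y_WP + (1−λ) y_PD operates on z-scored component
predictions (moments taken from the fitting set). Both components are
scale-free under the correlation criterion, so mixing raw outputs of
different magnitudes would make λ uninterpretable; standardization makes
λ = 1 and λ = 0 reproduce each component up to a positive affine map,
which the correlation criterion cannot distinguish. λ is a 0.01-step grid
search with ties resolved toward the larger λ (the windowed component
dominates empirically). Participants split at λ > 0.9 into
window-dominated (group 1) and mixed (group 2) evaluators.

## Synthetic participants: what they emulate

Defaults are the study conditions: 500-picture pools, two integer session
ratings averaged to the half-point grid, test-retest Pearson correlation
0.75, a small familiar fraction excluded from sequences; 96 four-picture
trials over seven sequence types and 36 seven-picture trials over peak
types; five continued sessions of 100 pictures with queries at uniform
8–13-picture intervals (the last interval re-drawn until the total is
exactly 100, so the final query always covers all 100 pictures); one
working-memory position probe per fixed-length trial with per-group
accuracy defaulting to (0.9, 0.8, 0.6, 0.7). The default ground-truth
evaluator is windowed preference-dependent with L = 10 — the window length
participants' selections cluster at, being the mean evaluation period of
the continued task — with mild preference amplification knots
(−0.05, −0.02, 0, 0.03, 0.08) and rating noise SD 0.5 on the 1–9 scale.

Generator mechanisms the tasks do not pin down, chosen once:

- Test-retest structure is a latent uniform preference plus independent
  integer-rounded Gaussian session noise; the noise variance is solved
  from the target correlation with a 1/12 correction for rounding.
- Remembered-utility noise is Gaussian on the rating scale before
  clipping and integer rounding; a `discretize` switch turns the rounding
  off for recovery studies where grid rounding would itself act as noise.
- Mean-type evaluators are scaled to weighted-mean form (identity for the
  basic estimators), which keeps outputs on [1, 9] per sequence.
  Discounting evaluators have no fixed per-sequence range, so their affine
  map onto [1, 9] is calibrated per task batch; this keeps generated data
  affine-equivalent to the raw discounted sums that the fits optimize,
  which is what makes noiseless self-recovery exact.
- Monotone sequences draw from the whole pool and sort; zigzag alternates
  a high (≥5) and a low (≤3) partition with random starting direction;
  peak-k takes its peak from the top partition and all non-peak items from
  one lower partition, giving them similar preference values.
- Preference partitions: the seven-way split minimizes the half-interval
  group sizes subject to the four full-interval groups staying within
  ±20% of each other, found by exhaustive search over the C(16, 6)
  contiguous boundary placements on the 17 rating levels (cheap, and
  globally optimal for the stated criterion, where a greedy scan would
  only approximate it).

What passing recovery tests show — and what they do not: the fits
faithfully invert the generator across its families (weights, window
sizes, discount rates, mixture λ at the endpoints), so failures on real
data would indicate model misfit rather than broken estimation. They do
not show that real participants follow any of these evaluators: human
remembered utilities carry structure the generator omits (sequential
dependencies between trials, attention lapses, idiosyncratic rating-scale
use, memory effects beyond a preference-dependent probe accuracy).
Two empirical regularities are reproduced only qualitatively on cohorts:
the basic-estimator ordering (Average > Peak-End > Peak/End) and the drop
in correlations on zigzag sequences, the latter requiring a ground truth
with order structure (a window shorter than the sequence, e.g. L = 3 on
4-picture trials).

λ-endpoint recovery is run noiseless: at rating-noise SD ≥ ~0.3 the WP and
PD predictions correlate around 0.9 and the mixture optimum moves off the
endpoints — λ is then only weakly identified, which is a property of the
model family, not of the optimizer.

## Problem sizes

Desk-scale defaults keep every fit comfortably interactive: cohorts of up
to 66 participants for qualitative orderings; 20 seeds for recovery
distributions; gradient-descent caps of 5,000–20,000 iterations (the
adaptive step typically converges in a few hundred); window search capped
at k = 49 by the 30-sample rule. The "simultaneous" criterion in the PCA
regression (sum of per-rate p-values below 0.05) is implemented literally
as specified by the analysis it mirrors and is flagged as non-standard;
reported p-values are raw, with no multiple-comparison correction.

## Known limitations

- The nested/hierarchical windowed-averaging idea (chunked periods inside
  a higher-level window) is deliberately out of scope.
- The recurrent-network reading of PD is an equivalence, not a trained
  model.
- Six-group SSE analyses use equal-size quantile bins with ties broken by
  input order; WM-vector variance uses the population convention
  (switchable via `ddof`).
- Per-participant correlations are compared by paired t-tests without
  Fisher z-transform by default (`fisher_z` is provided for the
  transformed variant).
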