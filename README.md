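# retroeval

Models of how people retrospectively evaluate sequences of experiences —
and a synthetic behavioral-task generator to validate every fit by
parameter recovery.

## The problem

After a dinner, a movie, or a stream of pictures, people compress the whole
experience into a single *remembered utility* y — a retrospective rating.
How does y arise from the *moment utilities* x_1, …, x_t of the individual
events? The classical peak-end rule claims y is driven by the most intense
and the final moments; plain averaging claims every moment counts equally.
`retroeval` implements a ladder of evaluation models of the form
y(t) = f(x_1, …, x_t), fitted by maximizing the Pearson correlation
ρ = corr(y_model, y) (equivalently, minimizing the MSE of the optimally
affine-rescaled prediction, since MSE/s_y² = 1 − ρ²):

- **Basic estimators** (no parameters):
  Peak = max_i x_i, End = x_t, Peak-End = (Peak + End)/2,
  Average = (1/t) Σ x_i.
- **Weighted-sum models** y = Σ w_i x_i with w_i = 1/n + w_{o,i} (weights
  indexed by temporal *position*) or w_i = 1/n + w_{p,i} (indexed by
  within-sequence preference *rank*), their λ-mixture
  w_i = 1/n + λ w_{o,i} + (1−λ) w_{p,i}, and absolute-preference weights
  w_i = 1/n + f(x_i) that depend on the moment's own utility (four
  partition bins, or a 17-level function interpolated from 5 free knots).
- **Windowed evaluation**: any of the above restricted to the last L
  moments, with L selected per participant by
  L = argmax_k corr(y_k, y) over leave-one-trial-out (jackknife) mean
  correlations, skipping candidates with fewer than 30 usable trials.
- **Discounting models**: simple discounting
  y_SD(t) = Σ_k r^{t−k} x_k (End at r = 0, Average at r = 1) and
  preference-dependent discounting y_PD(t) = Σ_k r(x_k)^{t−k} x_k, whose
  rate r(x) is interpolated from 5 free knots — so a highly preferred
  moment far in the past can keep weight that a recent mediocre one loses.
  Fitted by projected gradient descent on the SSE of the rescaled
  prediction a·y + b (a, b closed-form). The PD sum is also implemented as
  an equivalent recurrent network (one leaky accumulator per preference
  level) used as a cross-check.
- **Combined WP-PD model**: y = λ y_WP + (1−λ) y_PD on standardized
  component predictions, with participants split at λ = 0.9 into
  window-dominated and genuinely mixed evaluators.

Because the behavioral datasets these tasks come from are not publicly
archived, the package ships a first-class `synthetic_data` module that
emulates the tasks end to end: per-participant picture pools with
calibrated test-retest reliability (~0.75) on a 1–9 half-point grid,
seven-way preference partitions, seven sequence types, 100-picture
"continued" sessions queried every 8–13 pictures, and working-memory
position probes with preference-dependent accuracy in the observed
0.55–0.95 band.

## Worked example

```python
from retroeval import (
    ParticipantConfig, generate_participant,
    peak, end, peak_end, average, correlation_test,
    select_window_size, fit_windowed_preference_weights,
    fit_discounting, fit_wp_pd_mix,
)

data = generate_participant(ParticipantConfig(seed=42))
y = [t.remembered_utility for t in data.seq4]
for name, fn in [("peak", peak), ("end", end),
                 ("peak-end", peak_end), ("average", average)]:
    r = correlation_test([fn(t.sequence) for t in data.seq4], y).pearson
    print(f"{name:9s} rho = {r:+.4f}")

spec = select_window_size(data.continued, "preference_dependent", max_k=49)
wp = fit_windowed_preference_weights(data.continued, spec.L)
pd = fit_discounting(data.continued, "PD", max_iter=5000)
mix = fit_wp_pd_mix(data.continued, wp, pd)
print(f"selected window L = {spec.L}")
print(f"WP rho = {wp.correlation:.4f}, PD rho = {pd.correlation:.4f}")
print(f"combined WP-PD: lambda = {mix.lam:.2f}, rho = {mix.correlation:.4f}")
```

prints

```
peak      rho = +0.3964
end       rho = +0.3674
peak-end  rho = +0.4475
average   rho = +0.8688
selected window L = 13
WP rho = 0.8414, PD rho = 0.8432
combined WP-PD: lambda = 0.48, rho = 0.8560
```

The participant's remembered utilities were generated by a windowed
preference-dependent evaluator (window 10) plus rating noise, and the fits
read that structure back out: averaging beats the peak/end heuristics on
the 4-picture trials, the selected window lands near the generating one,
and the combined model edges out both of its components on the long
continued sessions.

A command-line interface mirrors the library:

```sh
retroeval simulate --seed 3 --out data/
retroeval fit --trials data/continued.csv --schema continued --model sd
retroeval run --config cfg.yaml --out out/   # simulate + fit + report.json
```

## Layout

- `retroeval.core` — domain types, trial-table I/O, preference partitions
- `retroeval.synthetic_data` — the task generator
- `retroeval.estimators` — basic + windowed estimators, window selection
- `retroeval.linear_models` — weighted-sum and preference-weight fits
- `retroeval.discounting` — SD/PD models, gradient fitting, WP-PD mixture
- `retroeval.stats` — correlation tests, sign test, WM analyses, PCA regression
- `retroeval.pipeline` / `retroeval.cli` — orchestration and the `retroeval` CLI

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
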