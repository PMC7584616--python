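# Methods

## Model and assumptions

The dichotomized CGM process `h_k ∈ {0,1}` is assumed stationary with
Bernoulli marginal `p_h` and AR(1) autocovariance
`cov[h_k, h_l] = α^|l−k| p_h(1−p_h)`, `0 ≤ α < 1`. This is an assumption
about the *dichotomized* series only; raw glucose is typically better
described by higher-order autoregressions, but thresholding flattens that
structure into approximately exponential decay of the indicator
autocovariance. Everything downstream — the closed-form error SD, the
finite-trial (tail-effect) correction, duration planning — is exact under
this model and approximate on real data to the extent the model holds.
Negative correlation (alternating chains) is excluded: glycemic episodes
persist, so `α ≥ 0`.

Both closed forms are validated in the test suite against brute-force
double sums over the explicit covariance matrix `σ² α^|k−l|` (relative
tolerance 1e−10 on grids up to n = 50 and n ≤ N ≤ 40), which is the
independent oracle for the algebra.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `p_h` | probability a sample is in range | — | dimensionless, [0, 1] |
| `α` | AR(1) autocovariance decay per lag | — | dimensionless, [0, 1) |
| `T_s` | CGM sampling period | 300 s | 288 samples/day |
| glycemic range | half-open `[lower, upper)` mg/dL | TBR `(−∞, 70)` | presets `tbr`, `l2h` `(−∞, 54)`, `tir` `[70, 180)`, `tar` `[180, ∞)` |
| `max_lag` | largest autocovariance lag fitted | 50 samples (~4 h) | the initial exponential decay; longer lags are noise-dominated |
| WNLLS weights | weight of lag τ in the α fit | `N − τ` (pair count) | estimator variance grows as pairs shrink; `uniform` available |
| population rules | aggregation of per-subject fits | mean `p̂_h`, 95th-pct `α̂` | high quantile: the most correlated traces dominate the population error at large n |

All core functions return dimensionless fractions; only the planning table
and the CLI multiply by 100, which prevents silent double scaling.

## Estimation conventions

- `p̂_h = t(N)`, the whole-recording fraction in range.
- Sample autocovariance `COV_h(τ)` subtracts the global mean in both
  factors and divides the lag-τ product sum by `(#pairs) − 1`; for one
  contiguous series that is `N − τ − 1`, so lag 0 is the unbiased sample
  variance. Recordings split at sensor gaps (> 1.5 sampling periods) pool
  product sums per segment without bridging the gap — bridging would
  corrupt the lag structure.
- `α̂` minimizes `Σ_τ w_τ (α^τ − COV_h(τ)/COV_h(0))²` over `α ∈
  [0, 0.999999]` (trust-region least squares, started at the clamped lag-1
  normalized covariance, tolerances 1e−15). The fit is on the linear scale
  because normalized covariances can be ≤ 0 at long lags where a log
  transform is undefined; log display is presentation only. If every lag
  ≥ 1 is non-positive the series is indistinguishable from white noise:
  `α̂ = 0` with a flag.
- Subjects whose trace never (or always) enters the range are flagged
  degenerate (`α` undefined) and excluded from population aggregation.
- Percentiles use linear interpolation between order statistics (numpy
  default), stated for reproducibility.

## Empirical error curves

Window errors `e(n; i) = t(n; i) − t(N)` are computed over all
`M = N − n + 1` overlapping windows (stride 1) via prefix sums — value
identical to direct averaging, O(N) per window length. The pooled SD
divides `Σ e²` by `M − 1` *without centering* (root mean square about
zero); the pooled mean is reported separately and is near zero by
unbiasedness. With unequal trace lengths each subject contributes windows
against its own `t(N)` and window lengths are capped at the shortest trace.

## Simulator

`chain_from_targets` inverts the stationary relations exactly, so simulated
processes have exactly known `(p_h, α)` — the ground truth for validation.
The initial state is drawn from the stationary distribution, making the
process stationary from the first sample; burn-in is therefore unnecessary
and defaults to 0 (a parameter exists for sensitivity checks). Each
replicate uses an independent substream spawned from the master seed, so
results are independent of replicate ordering. The replicated Monte-Carlo
SD uses the true `p_h` and the `N_rep − 1` denominator.

Simulated binary traces can be encoded as synthetic glucose traces (a
representative value inside the range for 1, outside for 0) so simulated
cohorts flow through the same CSV/dichotomization path as real data.

## Numerical choices

- `αⁿ` is evaluated directly; for large `n` it underflows to exactly 0,
  which is the correct asymptote (verified up to n = 10⁶).
- The finite-trial variance can come out a tiny negative number near
  `n = N` from floating cancellation; it is clamped to 0, the exact value
  there.
- Duration planning brackets exponentially, bisects, then scans ±1 sample,
  because the `−2α/n·(…)` correction makes the error SD not strictly
  monotone at very small `n`.
- `p_h ∈ {0, 1}` yields `sd[e(n)] = 0` (degenerate, not an error): the
  case arises naturally in simulated traces.

## Problem sizes used in the validation suite

Monte-Carlo checks use 1000 replicated traces of 1000 samples
(`α = 0.86`, `σ² = 0.024`); parameter recovery uses 10 simulated subjects
of 51840 samples (6 months at 5-min sampling) per cell of a 3×3 grid
(`p_h ∈ {0.043, 0.1, 0.3}` × `α ∈ {0.5, 0.8, 0.917}`, each recovered
within 0.02 on the across-subject mean); the empirical tail-effect check
uses 100 traces of 8640 samples (30 days) at the population parameters.
At 1000 replicates the Monte-Carlo SD of `SD[e(n)]` is itself ≈8–10%
relative at small `n` for rare events (`p_h ≈ 0.025`), so individual-seed
deviations of that order from the closed form are expected and do not
indicate bias; the across-seed mean gap is below 1.5% at every `n`.

## Known limitations

- The generator emulates the *dichotomized* process only: no meal/insulin
  dynamics, sensor noise, dropout patterns, circadian structure, or
  between-day variance. Passing tests show the formulas are correct under
  the AR(1) model, not that real cohorts satisfy it; that evidence must
  come from fitting real traces (`cgmplan fit`) and inspecting the
  exponential fit quality.
- A single exponential cannot capture mixtures of short and long
  hypoglycemic episodes; `α̂` then reflects the dominant decay at lags
  ≤ `max_lag`.
- The planning table at rounded population parameters gives 2.165% → 2.2%
  for a 7-day window; published tabulations based on unrounded parameters
  may show 2.1%. The package always reports the formula value at the
  parameters given.
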