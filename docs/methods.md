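# Methods note

This note documents the models implemented in `budchill`, the default
parameters and why they were chosen, what the synthetic-study generator
does and does not emulate, and the numerical conventions used
throughout. All numbers quoted here are either model constants or were
computed by the package itself (see `scripts/acceptance.py` and the
test suite); no other empirical claims are made.

## 1. Thermal accumulation models

All models consume a strictly hourly temperature series
(`HourlyTemperatureSeries`); gaps up to 6 hours may be linearly
interpolated at ingest, longer gaps are rejected.

### Chill hours (CH)

One unit per hour with `low < T ≤ high`; defaults `low = 0 °C`,
`high = 7.2 °C`, the classical chill-hour band. Both bounds are
configurable arguments.

### Chill portions (CP, dynamic model)

Two-step kinetics: a thermally labile intermediate accumulates toward a
temperature-dependent equilibrium, is destroyed by warmth, and is
irreversibly converted ("banked") to a chill portion once it reaches
one unit. Per hour at `TK = T + 273`:

```
sr    = exp(slp · tetmlt · (TK − tetmlt) / TK)
xi    = sr / (1 + sr)
xs    = (a0 / a1) · exp((e1 − e0) / TK)
decay = exp(−a1 · exp(−e1 / TK))
x     = xs − (xs − carry) · decay
if x ≥ 1:  portions += xi · x ;  carry = (1 − xi) · x
else:      carry = x
```

Constants (canonical, exposed in `DynamicModelParams`): `slp = 1.6`,
`tetmlt = 277`, `a0 = 1.395e5`, `a1 = 2.567e18`, `e0 = 4153.5`,
`e1 = 12888.8`. The temperature-dependent terms are vectorized; only
the banking recursion is a Python loop. The implementation is verified
against an independent hour-by-hour scalar transcription of these
equations to 1e-9 over 1,000 random hours.

### Growing degree hours (GDH, ASYMCUR)

Asymmetric cosine response with base `4 °C`, optimum `25 °C`, critical
`36 °C`, stress factor `F = 1`:

- base < T ≤ opt: `F · (opt−base)/2 · (1 + cos(π + π(T−base)/(opt−base)))`
- opt < T ≤ crit: `F · (opt−base) · (1 + cos(π/2 + π/2 · (T−opt)/(crit−opt)))`
- zero outside (base, crit].

Both branches equal `21.0` GDH at the optimum, giving a continuous
response; anchor values (0 at base and critical, 21 at optimum) are
asserted in tests.

## 2. Phenology

The endo→eco **transition date** is estimated from a forcing assay: for
each cutting date, replicate budbreak-stage scores observed after the
forcing horizon are aggregated (median by default; `min` and `any` also
available) and the earliest cutting date whose aggregate reaches the
stage threshold (default 59, i.e. most buds open) is taken as the
transition. Defaults: horizon 5 weeks, threshold 59.

- **Chilling requirement**: CH or CP accumulated over
  `(season_start, transition]`.
- **Heat requirement**: GDH accumulated over `(transition, budbreak]`,
  reported as a min/max range over the observed budbreak window.

## 3. qPCR relative expression (2^−ΔΔCt)

1. **QC**: samples or assays whose mean quality falls below the
   threshold (default 0.65) are removed whole, with a reasoned
   exclusion log; an empty remainder is an unusable plate (error).
2. Technical replicates are averaged **on the Ct scale** first.
3. `ΔCt = Ct(target) − mean Ct(references)`;
   `ΔΔCt = ΔCt(sample) − ΔCt(calibrator)`; `rel_expr = 2^−ΔΔCt`.
4. **Profiles**: two-stage averaging — technical within biological
   replicate, then across biological replicates — so unbalanced designs
   weight each biological replicate equally.

**Reference stability**: for ≥ 2 candidate references, the package
reports a geNorm-style expression-stability M and the comparative ΔCt
method's mean pairwise SD. With an assumed 2-fold amplification
efficiency these two statistics are numerically identical; both are
still reported, and candidates are ordered by the geometric mean of
their ranks (a comprehensive rank). Candidates missing in more than
20 % of samples are excluded with a reason.

## 4. Trajectory clustering

Gene × timepoint profiles are interpolated over interior gaps, genes
missing more than 30 % of timepoints are dropped (logged), and rows are
z-scored (zero-variance rows become all-zeros). k-means
(`init="random"`, one initialization per restart) is run `n_starts`
times (default 25) with deterministic sub-seeds derived from the master
seed, and the solution with minimal within-cluster sum of squares (WSS)
is kept. Labels are canonicalized by sorting centroids by the time of
their maximum (ties broken by cluster size), so identical data yield
identical labels regardless of restart order. A WSS curve over a k
range with a second-difference elbow supports choosing k (k = 1 equals
the total sum of squares).

## 5. Expression–temperature correlation

Covariates per sampling date (window default 14 days, ending at 23:00
of the sampling date): mean daily temperature, windowed CH, CP and GDH
sums. Windows truncated by the series start are flagged and excluded by
default. Pearson r with two-sided p (and least-squares slope/intercept)
is computed pooled across cultivars, per cultivar, or both. Groups with
fewer than 3 points or zero variance are reported with a reason instead
of a coefficient. Pooling cultivars that share a temperature slope but
differ in expression level attenuates |r|; the per-cultivar grouping
exposes this, and `fit_line_by_group` reports the slope difference for
two-group designs.

## 6. Synthetic study generator

### What it emulates

- An hourly temperature season (default 2017-09-01 → 2018-05-31):
  seasonal + diurnal sinusoids plus AR(1) noise. Defaults
  (`annual_mean_c = 10.5`, `seasonal_amplitude_c = 9.3`,
  `diurnal_amplitude_c = 3.5`, `coldest_doy = 15`, `ar1 = 0.85`,
  `noise_sd_c = 1.2`) describe a cool temperate orchard winter in which
  the default cultivars' chill thresholds are met in mid-to-late
  January.
- Per-cultivar dormancy: the transition occurs when cumulative CP
  crosses the cultivar's threshold (defaults 72.9 for Pinova, 83.9 for
  Gala), budbreak when 2750 GDH have accumulated after the transition.
- A forcing assay (weekly cuttings Dec 5 → Feb 27, 3 replicates,
  5-week horizon) with a 2 % per-replicate stage-misclassification
  probability.
- A qPCR plate: 28 weekly samplings from Sept 20, 2 cultivars ×
  3 biological × 2 technical replicates; planted gene archetypes
  (endodormancy peak, late-endodormancy peak, two-peak, ecodormancy
  peak, broad, budbreak-induced), temperature-coupled genes (linear in
  14-day mean daily temperature, optionally with cultivar-specific
  slopes/intercepts), stable reference genes at Ct ≈ 20, biological
  (SD 0.4) and technical (SD 0.15) Ct noise, and planted low-quality
  units (one bad sample and one bad assay by default, quality ≈ 0.45
  vs ≈ 0.95).
- Full ground truth (transitions, budbreak windows, cluster labels,
  coupling slopes, calibrator-normalized latent trajectories) is
  returned so every analysis stage can be validated.
- Determinism: every random stream derives its child seed from the
  master seed and a stable stream name, so identical configurations
  produce byte-identical outputs.

### What it does not emulate

- No weather fronts, cold snaps or inter-annual climate trends — noise
  is stationary AR(1) around smooth sinusoids.
- No amplification-efficiency variation, primer-dimer artifacts,
  plate/batch effects, or Ct censoring at the detection limit (latent
  expression is floored at 0.05 before log-transform instead).
- Dormancy release is a hard threshold, not a gradual probabilistic
  transition; all buds of a cultivar share one threshold.
- Reference genes are truly stable by construction; regulation of
  references is not simulated.

## 7. Numerical conventions

- All accumulation intervals are half-open `(start, end]`, so adjacent
  windows tile without double counting; `accumulate_between` is
  therefore additive over abutting intervals.
- Banking in the dynamic model is order-dependent and implemented as a
  strict forward recursion; cumulative series are float64 throughout.
- z-scoring uses population SD (ddof = 0); zero-variance genes map to
  zero vectors rather than NaN.
- k-means sub-seeds are taken from `SeedSequence(seed)` reduced modulo
  2^31 − 1 to stay in the range accepted by the backend.
- JSON manifests are written with sorted keys and no timestamps to keep
  outputs byte-reproducible.

## 8. Problem sizes exercised in validation

The test suite validates the stages at, among others: 1,000-hour random
series against the kinetics oracle; 20 simulated winters for phenology
recovery; 36 genes / 6 archetypes for clustering (adjusted Rand ≥ 0.9);
200 simulated campaigns for correlation power and null calibration; and
100 two-cultivar campaigns for pooling attenuation. The full default
pipeline (≈ 6,500 hours, 39 genes, 168 samples) runs in a few seconds.

## 9. Limitations

- CP/GDH constants are treated as universal; no cultivar-specific
  recalibration of the thermal models is provided.
- The transition estimate has one-sampling-interval (weekly)
  resolution; requirement estimates inherit that granularity.
- The elbow heuristic is a suggestion only; k should be confirmed
  against the WSS curve and biological interpretability.
- Correlation analysis is univariate per covariate; no multiple-testing
  correction is applied to the report (p-values are raw).
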