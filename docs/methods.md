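# Methods

## Scope and model

`pulsetransit` estimates per-beat pulse wave transit time (PWTT) between
two synchronously sampled pulmonary artery pressure channels and relates
it to per-beat systolic/mean/diastolic pressure (sPAP/mPAP/dPAP). The
measurand is a *difference of foot times*: the absolute localisation of a
single channel's pulse foot is allowed to be biased, as long as the bias
is identical on both channels. The whole design follows from that
observation — both channels always pass through bit-identical filter
chains.

### Pulse arrival: intersecting-tangent foot

For each beat the arrival is the intersection of the tangent at the
maximum systolic upstroke with the horizontal through the preceding
diastolic pressure:

    t_arrival = t_up − (p_up − p_foot) / s_up

with `t_up` the local maximum of the smoothed derivative, `p_up` the
smoothed pressure there, `s_up` the smoothed derivative there, and
`p_foot` the minimum of the smoothed pressure in the 0.3 s window ending
at `t_up` (ties resolved toward the latest sample). The tangent method is
used (rather than maximum-upstroke or local-minimum feet) for robustness
against morphology changes between sites. Arrival is continuous-valued,
not snapped to the sample grid, keeping transit resolution below the
0.1 ms sample period. This construction is scale- and offset-invariant:
multiplying a channel by a positive constant or adding a constant leaves
`(p_up − p_foot)/s_up` unchanged, so amplitude differences between sites
do not perturb the transit time.

### Filter chain and its bias

Pressure is smoothed with a centred moving average over 1000 samples
(100 ms at the 10 kHz reference rate; windows scale with the sampling
rate to preserve their time span), differentiated by central differences,
and the derivative smoothed over 100 samples. Centred alignment with
reflect padding was chosen because a causal (one-sided) average would add
a group delay that cancels between channels anyway, but behaves worse at
recording edges.

A 100 ms smoothing span is larger than a typical 80 ms systolic upstroke.
On the synthetic template this halves the maximum slope and shifts the
single-channel tangent foot by about −21 ms relative to the closed-form
tangent foot of the unfiltered waveform. The shift is *constant across
beats and channels* (measured SD across beats < 0.1 ms on clean input),
so it cancels exactly in PWTT; tests assert both the constancy and the
cancellation (a pure 40 ms inter-channel shift is recovered to within one
sample period). Users who need accurate *absolute* feet (e.g. for
ECG-referenced pulse arrival time) should reduce `pressure_window` to
roughly a quarter of the upstroke duration; at `pressure_window=200`,
`derivative_window=20` the absolute foot error on clean input is below
1 ms. This tension between the literal reference windows and upstroke
duration is inherent to the recipe, not an implementation artifact.

### Beat pressures, exclusions, matching

sPAP/mPAP/dPAP are the max/time-mean/min of the **raw** channel over the
window between consecutive arrivals (the last beat has no closing
boundary and is dropped). Exclusion rules, both configurable:

- *Premature beats*: RR below 0.8x the median RR of the surrounding 11
  beats; the beat and its successor are invalidated (the successor's
  diastolic reference is corrupted). The criterion in the original
  processing was subjective; this rule is declared, not inferred.
- *Artifacts*: beats whose pulse amplitude (sPAP−dPAP) or upstroke slope
  deviates from the channel median by more than 5 median absolute
  deviations. The MAD is floored at 0.1% of the median so that noiseless
  recordings (MAD ~ float epsilon) are not mass-flagged; a side effect is
  that the first beat of a clean recording is excluded as a boundary
  artifact, which is intended — it lacks a preceding diastolic decay and
  its smoothed upstroke genuinely differs.

Matching is greedy: each distal arrival takes the latest proximal arrival
strictly earlier than it within 150 ms, each proximal beat used once.
Pairs outside the physiological 2–150 ms transit band are rejected and
counted. Wave velocity `PWV = D/PWTT` is reported only when the sensor
separation `D` is known; values outside 0.5–12 m/s are logged, not fatal.

## Statistics

Per animal and pressure type, ordinary least squares of PWTT (ms) on
pressure (mmHg). `r` carries the slope's sign; the regression F-test uses
the identity `F = r²(n−2)/(1−r²)` on (1, n−2) degrees of freedom, which
is asserted as an invariant of every emitted result. A perfect fit
reports `F = inf, p = 0`.

Group pooling applies Fisher's variance-stabilising transform
`z = atanh(|r|)` per animal, averages, and back-transforms. The default
is the **unweighted** mean of z: feeding the published per-animal r² of
both treatment groups through it reproduces all six published pooled
coefficients to <0.001, whereas the (n−3)-weighted mean (also provided as
`nz_weighted_z_mean`) does not — e.g. 0.703 vs the published 0.742 for
systolic pressure under the drug infusion. The dispersion reported
alongside is the sample SD of the per-animal |r|, labelled as such; it
reproduces one of the six published "±" values but not the other five,
and no standard formula we tried (SD of r, SD of z, SE of the weighted z
mean) matches them all, so the field is descriptive only.

Differences between the three pressure types are tested with a one-way
repeated-measures ANOVA on the z values (variance-stabilised scale;
animals as the repeated unit), partitioning sums of squares into
condition, subject and residual, followed by all three paired t contrasts
with Holm correction. The implementation is checked in tests against
statsmodels' `AnovaRM` and against hand-computed sums of squares.

The linear-vs-quadratic comparison fits degree-1 and degree-2
polynomials and prefers by AIC (`n ln(RSS/n) + 2k`). AIC admits a
spurious quadratic term with asymptotic probability P(χ²₁ > 2) ≈ 0.16, so
on truly linear data the linear model is preferred in roughly 82–84% of
replicates — an inherent property of the criterion, asserted as such.

## Synthetic data generator

The generator emulates the validation experiment's conditions, not a full
cardiovascular model. Per beat:

- RR intervals are lognormal (mean 60/HR, CV `heart_rate_cv`, defaults
  90 bpm and 0.03 for an anaesthetised pig).
- Systolic/diastolic endpoint pressures follow a linear ramp
  (drug-infusion scenario) or a rise–plateau–return profile (hypoxic
  episode) between configurable baseline and target values, plus
  independent per-beat Gaussian jitter (`pressure_jitter_sd`, default
  0.8 mmHg). The independent jitter is what decorrelates the systolic and
  diastolic trajectories; without it the two ramps are collinear and the
  observed ordering of correlation strengths across pressure types could
  not emerge.
- The true transit time is `a − b·sPAP` (defaults a = 70.945 ms,
  b = 0.481 ms/mmHg, in the published per-animal range) plus Gaussian
  jitter (default 1.5 ms — a deliberate guess that makes recovery tests
  non-trivial, since no beat-level variance at fixed pressure has been
  reported), clipped at 5 ms. The law is driven by systolic pressure;
  mean/diastolic correlations emerge through their correlation with it.
- The beat template is a raised-cosine upstroke (closed-form maximum
  slope π·(p_sys−p_dia)/(2·rise), used as an analytic oracle) followed by
  an exponential decay whose time constant is solved so the pressure
  lands exactly on the next beat's diastolic level; the train is
  C0-continuous. No dicrotic notch, no reflected waves, no respiratory
  modulation.
- The distal channel renders the same beats foot-aligned at
  `t_foot + PWTT_i` with pulse amplitude scaled by
  `distal_pulse_amplification` (default 0.9, peripheral damping).
- Premature beats (per-beat probability, default 0 except 0.02 in the
  default cohort) arrive after 0.6x the running-mean RR with 30% less
  pulse amplitude; both constants are configurable and exist to exercise
  the exclusion rule.
- White Gaussian measurement noise (default 0.5 mmHg) is added per
  channel after ground truth is extracted.

The default six-animal cohort anchors each animal's baseline/peak
pressures and transit-law coefficients to the published animal-level
values (four of six with a sensor distance back-computed from published
baseline transit time and velocity; one deliberately without, to exercise
the missing-distance path). Each animal records 240 s (~345 valid beats),
comparable to the published 290–1600 beats per animal.

### What passing tests do and do not show

Ground-truth recovery on this generator demonstrates the pipeline's
correctness (foot localisation, cancellation of filter bias, matching,
exclusion logic, statistics), not field performance on real recordings:
real pulmonary pressure waves carry dicrotic notches, respiratory and
ventilation modulation, reflected waves, baseline drift and
morphology-dependent distortion between sites, none of which are
simulated. One known systematic effect is visible even in simulation:
with measured pressures taken from the distal site (the default,
configurable via `pressure_source`), the 0.9 amplitude damping rescales
the pressure axis and biases recovered slopes upward by ~6–11% depending
on each animal's diastolic co-ramp; using the proximal site removes it.

## Numerical choices and degenerate inputs

- Windows are integers in samples; at non-reference sampling rates they
  scale to preserve 100 ms / 10 ms spans, floored at one sample.
- Upstroke picking requires peaks ≥ 0.3x the 95th percentile of the
  positive smoothed derivative and ≥ 0.25 s separation; a constant
  channel yields an empty event list, not an error.
- Zero pressure variance, |r| = 1 pooling inputs, incomplete ANOVA
  matrices, windows longer than the signal, and non-physiological
  template parameters raise `ValueError` with specific messages.
- Determinism: one `numpy` Generator seeded from the config; identical
  configs give bit-identical recordings, and pipeline runs write
  byte-identical tables.

## Known limitations

- Absolute (single-channel) foot times under the default windows are
  biased (see above); only transit differences are calibrated.
- The premature-beat and artifact rules are simple declared heuristics;
  sensitivity/specificity are measured against the generator's ectopy
  model only.
- The published "±" dispersion values could not be reproduced by any
  standard formula and are excluded from validation.
- One published regression row (drug-infusion animal 4, mean pressure)
  has an F value inconsistent with its printed r² and n under the F
  identity; it is carried as printed and excluded from consistency
  checks.
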