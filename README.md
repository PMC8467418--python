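# pulsetransit

Pulse wave transit time (PWTT) extraction from dual-site pulmonary artery
pressure waveforms, and its correlation with systolic, mean and diastolic
pulmonary artery pressure (sPAP/mPAP/dPAP).

## The problem

Pulmonary hypertension is diagnosed and monitored with invasive right
heart catheterisation. A promising non-invasive surrogate is the time a
pressure pulse needs to travel between a proximal and a distal site in
the pulmonary artery tree: as distending pressure rises the vessel wall
stiffens and the pulse propagates faster, so transit time falls. This
package implements, as a tested reusable pipeline, the reference
processing chain used to validate that relationship invasively in a
porcine model:

1. **Filtering** — centred moving average on each raw pressure channel
   (100 ms span at 10 kHz), first derivative, second moving average
   (10 ms span).
2. **Upstroke detection** — local maxima of the smoothed derivative, one
   per cardiac cycle (minimum separation and prominence guards).
3. **Pulse arrival** (*intersecting-tangent foot*) — the intersection of
   the tangent at the maximum systolic upstroke with the horizontal line
   through the preceding diastolic pressure:
   `t_arrival = t_up − (p_up − p_dia) / (dp/dt)|_up`.
4. **Transit and velocity** — `PWTT = t_arrival,distal − t_arrival,proximal`
   (ms); with a known sensor separation `D`, `PWV = D / PWTT` (m/s).
   Premature beats (short RR vs the local median) and amplitude/slope
   outliers are excluded.
5. **Statistics** — per animal, ordinary least squares `PWTT = a + b·PAP`
   with the regression F-test `F = r²(n−2)/(1−r²)`; per treatment group,
   Fisher-z pooling of the per-animal correlation magnitudes
   (`r̄ = tanh(mean atanh|rᵢ|)`); across the three pressure types, a
   one-way repeated-measures ANOVA on the z values with Holm-corrected
   paired contrasts; and a linear-vs-quadratic AIC comparison.

Because no beat-level recordings from such experiments are publicly
deposited, the package ships a **synthetic waveform generator** with
exact per-beat ground truth (foot times, transit times, pressures,
premature flags): raised-cosine upstroke plus exponential diastolic
decay, configurable pressure ramps, a linear transit-pressure law,
noise, site amplitude scaling and ectopic beats. Every downstream stage
is validated against it.

## Worked example

```python
from pulsetransit import (SimulationConfig, simulate_experiment,
                          analyze_recording, TransitPressureModel)

cfg = SimulationConfig(duration=60.0, target_sPAP=43.7, target_dPAP=21.8,
                       premature_prob=0.02, seed=42)
experiment = simulate_experiment(cfg)          # two channels + ground truth
beats, pairs, counts = analyze_recording(experiment.recording)
print(counts)
res = TransitPressureModel.from_pair_table(pairs, "sPAP", "demo").fit()
print(res.summary())
```

prints

```
{'beats_detected_proximal': 87, 'beats_detected_distal': 87,
 'beats_valid_proximal': 87, 'beats_valid_distal': 87,
 'premature_flagged': 0, 'pairs_matched': 87, 'pairs_rejected': 0}
Transit-time vs pressure regression
===========================================
animal:        demo
pressure type: sPAP
n beats:       87
equation:      PWTT = 74.084 - (0.577 * sPAP)
r:             -0.8386
r^2:           0.7032
F(1, 85):    201.423
p:             3.87e-24
```

87 beats are detected and paired per channel (this seed happens to draw
no premature beats at the 2% rate), and the beat pairs give a strong
negative linear relation between transit time and systolic pressure —
the recovered slope (−0.577 ms/mmHg) sits close to the generating law
(−0.481 ms/mmHg, with the expected damped-distal-site bias; see
`docs/methods.md`).

The same flow is available from the shell:

```bash
pulsetransit run --default-cohort --seed 1 --out-dir out/
pulsetransit reproduce-published-stats
```

The first command simulates the default six-animal drug-infusion cohort
and writes beat tables, pair tables, per-animal regressions, the pooled
summary and a run manifest. The second recomputes the pooled group
correlations and the repeated-measures contrasts from the bundled
per-animal summary statistics of the porcine validation study.

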