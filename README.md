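# presacc

Behavioral modeling of **presaccadic selection**: how planning a rapid eye
movement changes visual change detection and orientation estimation at the
saccade target, analyzed with multidimensional signal detection theory and
Bayesian variable-precision observer models.

The package is written for visual-psychophysics researchers who run dual-task
paradigms — four peripheral Gabor stimuli, a saccade cue toward one of them,
and either a 5-alternative change detection/localization report or a
continuous orientation estimate — and want a tested, reproducible pipeline
from trial tables to model comparison. Every analysis also runs end-to-end on
synthetic observers, so the estimators can be validated by parameter recovery
without any experimental data.

## What it computes

**m-ADC signal detection** (`presacc.madc`). The 4-alternative
detection/localization observer has per-location sensitivities d′ and
thresholds t over independent unit-variance Gaussian decision variables; it
reports the location whose decision variable exceeds threshold by the largest
margin, or "no change". Response probabilities are exact one-dimensional
integrals; fits are maximum likelihood on the 5×5 stimulus-response
contingency table; the criterion (spatial choice bias) is c = t − d′/2.
Controls include a mislocalization-free 1-D SDT refit, χ² randomization
goodness of fit, saccade-locked temporal windows (50 ms bins centered −175 to
−25 ms), and a sliding hit+false-alarm time course.

**Estimation metrics** (`presacc.estmetrics`). Signed circular errors on the
180°-periodic orientation circle, MAE, precision (reciprocal non-parametric
circular SD after angle doubling), von Mises overlay fits, and the
recency/primacy bias: the signed area under a sliding-median bias curve
(60° bins, 1° steps) over ±[10°, 60°] of relative orientation — positive for
attraction toward the biasing stimulus.

**Variable-precision observers** (`presacc.vp_estimation`,
`presacc.vp_change`). Gamma-distributed encoding precision J with von Mises
measurement noise of concentration κ = φ(J) (Fisher-information convention).
Estimation: precision-marginalized predictive error densities with motor
noise, fitted jointly to initial-ST / final-ST / SA pooled error sets with a
shared scale τ; Kuiper goodness of fit. Change detection: a Bayesian ideal
observer whose posterior change odds at each location are
F = I₀(κ_x)I₀(κ_y)/I₀(√(κ_x² + κ_y² + 2κ_xκ_ycos(y−x))), with four variants —
baseline, perceptual (recency) bias B, choice bias (separate thresholds
η_ST, η_SA), and both — compared by AICc and leave-session-out
cross-validated likelihood.

**Statistics** (`presacc.stats`). Label-shuffling permutation tests (exact
for small samples), cluster-based permutation over time courses, JZS Bayes
factors with sequential analysis, Bonferroni–Holm correction, and an exact
implementation of Hartigan's dip test of unimodality.

**Synthetic data & pipeline** (`presacc.synthdata`, `presacc.pipeline`).
Generators for both tasks with the paradigm's statistical structure (cue
uniform over quadrants, 20 % change probability per location, truncated
geometric stimulus durations, ex-Gaussian saccade latencies, gaze-based
exclusion fields), and orchestration that runs exclusions → tables → fits →
group statistics and emits a JSON-serializable report.

## Worked example

Simulate one observer with matched sensitivity but a lower threshold at the
saccade target, and fit it:

```python
import numpy as np
from presacc import madc, synthdata, trials

observer = madc.MADCParams(d=[1.1, 1.15, 1.15, 1.15],
                           t=[0.61, 0.815, 0.815, 0.815])
session = synthdata.simulate_change_detection_session(
    observer, n_trials=4000, delta_theta=20.0, seed=7)
kept, report = trials.apply_gaze_exclusion(session)
table = trials.build_contingency_table(kept)
params, ll = madc.fit_madc(table)
print("kept", report["n_kept"], "of", report["n_input"], "trials")
print("d' toward", round(params.d[0], 2), "away", round(params.d[1:].mean(), 2))
print("c  toward", round(params.c[0], 2), "away", round(params.c[1:].mean(), 2))
```

Output:

```
kept 3524 of 4000 trials
d' toward 1.06 away 1.19
c  toward 0.1 away 0.23
```

The exclusion report shows the gaze criteria removing ~12 % of trials
(wrong-quadrant saccades, late saccades, unstable fixation, saccades
launched before the final stimulus set disappeared). The fitted sensitivities
are statistically indistinguishable between the saccade-target and away
locations, while the criterion is distinctly lower at the target — the
observer is biased toward reporting changes there, exactly the structure the
generator injected. `presacc.pipeline.run_change_detection_analysis` repeats
this per participant and adds permutation tests and Bayes factors at the
group level.

A thin CLI covers the common entry points:

```bash
presacc simulate-change-detection --n-trials 3000 --seed 7 --out trials.csv
presacc fit-madc trials.csv --out fit.json
presacc run --trials trials.csv --out report.json
```

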