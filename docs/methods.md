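# Methods

`presacc` models behavior in a dual-task paradigm in which an observer plans
a saccade to one of four peripheral Gabor stimuli while either (a) detecting
and localizing an orientation change at one of the four locations, or (b)
estimating the orientation of a probed stimulus from one of two briefly
presented stimulus sets. This note documents the models, the synthetic-data
generator, the numerical choices, and what the test suite does and does not
establish.

## Multidimensional signal detection (4-ADC)

The change-detection observer monitors four locations. On a trial with a
change at location *i*, the decision variable at location *k* is Gaussian with
unit variance and mean `d_i` if `k = i`, else 0. Each location carries a
threshold `t_k`; the observer reports the location whose decision variable
exceeds its threshold by the largest margin, or "no change" if none does.
Response probabilities reduce to one-dimensional integrals

    P(respond j | signal i) = ∫₀^∞ φ(z − μ_j) Π_{k≠j} Φ(z − μ_k) dz,
    μ_k = d_i·[k = i] − t_k,

evaluated with 200-node Gauss–Legendre quadrature on `(0, max μ + 9)`; the
no-change probability has the closed form `Π_k Φ(−μ_k)`. The criterion
(choice-bias) measure is `c = t − d′/2` per location; a lower criterion means
a stronger bias to report a change there.

Fitting maximizes the multinomial likelihood of the 5×5 stimulus-response
contingency table over `(d, t)` with bounded L-BFGS-B (`d ∈ [0, 5]`,
`t ∈ [−3, 5]`) from a deterministic five-point multistart schedule (a
1-D-SDT moment start plus four fixed starts); the best likelihood wins, so
fits are exactly reproducible. Goodness of fit is a parametric bootstrap of
the χ² statistic at the observed row totals (expected counts floored at
1e-6), with add-one smoothing of the p-value.

The one-dimensional control refit drops the mislocalization cells and
estimates per-location yes/no `(d′, c)` from hit and false-alarm rates with
the log-linear (add 0.5) correction for extreme rates.

Temporal analyses bin trials by the latency between the change event
(final-set onset) and saccade onset: non-overlapping 50 ms windows centered
at −175, −125, −75 and −25 ms for full refits (windows are half-open,
`[c − w/2, c + w/2)`, fitted independently; windows with fewer than 25 trials
are skipped), and overlapping 50 ms windows stepped by 5 ms from −200 to
+50 ms for the hit+false-alarm rate time course.

## Orientation-estimation metrics

Orientations are 180°-periodic; every circular statistic doubles the angles
onto the full circle, operates there, and maps back. The signed estimation
error is the minimal signed angular difference in `(−90, 90]`, with the ±90°
tie resolved to +90 deterministically. Precision is the reciprocal of the
non-parametric circular standard deviation `√(−2 ln R̄)` of mean-subtracted
errors (invariant to rotating all errors); exactly degenerate, zero-dispersion
samples return a capped precision of 100 with a flag. The display-overlay von
Mises fit estimates the concentration by solving `I₁(κ)/I₀(κ) = R̄`.

The recency/primacy bias statistic bins trials by the orientation of the
biasing stimulus relative to the probed one (60°-wide bins sliding by 1°,
with circular wraparound), takes the median signed error per bin, and
integrates the curve over ±[10°, 60°] of relative orientation with the sign
of the negative branch flipped, so attraction toward the biasing stimulus is
positive and repulsion negative. Empty bins inside the integration range
invalidate the statistic rather than being interpolated.

## Variable-precision (VP) observer models

Across trials the encoding precision *J* of each item is gamma distributed
with mean `J̄` and scale `τ` (shape `J̄/τ`). Given *J*, the internal
measurement is von Mises on the doubled circle with concentration
`κ = φ(J)`, where `J(κ) = κ·I₁(κ)/I₀(κ)` is the Fisher information of the
measurement; the inverse is computed by table lookup refined with Newton
steps. This convention makes `J` additive over independent measurements and
is the standard one in the VP literature.

**Estimation.** The predictive error density is the precision-marginalized
von Mises mixture, approximated by averaging 1,000 von Mises densities at
gamma quantiles of fixed uniform draws, on a 720-point grid over the doubled
circle, circularly convolved (FFT) with a motor-noise von Mises kernel of
fixed concentration `κ_m = 25`. Three pooled error sets — initial-set and
final-set errors at the saccade target (ST) and pooled errors at the other
(SA) locations — are fitted jointly by maximum likelihood with separate mean
precisions and a shared `τ`: a logarithmic grid (25 points over
`J̄ ∈ [0.05, 50]`, 20 over `τ ∈ [0.5, 50]`) followed by Nelder–Mead
refinement in log space. The same gamma quantile uniforms are reused for
every parameter evaluation (common random numbers), making the likelihood
surface smooth and the fit deterministic given its seed. Grid-boundary
solutions are flagged. Goodness of fit uses Kuiper's rotation-invariant V
with the standard asymptotic p-value.

**Change detection.** Measurements `x` (initial set) and `y` (final set) at
each location have their own gamma-drawn precisions; the final-set precision
at the ST location is a fixed multiple (default 6) of `J̄`, and `τ` (default
13) is imported from the estimation fit — both overridable. The posterior
odds of change at location *l* is proportional to

    F(l) = I₀(κ_x) I₀(κ_y) / I₀(√(κ_x² + κ_y² + 2 κ_x κ_y cos(y − x))),

computed with log-Bessel arithmetic; the observer reports "no change" unless
`F(l) > η_l` somewhere, else `argmax F(l) − η_l`. The task's 20 %-per-location
change prior is absorbed into the fitted thresholds rather than modeled
separately. Four variants differ in their free parameters: baseline (`J̄`,
η fixed at 1), perceptual bias (+ recency weight `B ∈ [0, 1]` applied to the
initial ST measurement as shortest-arc interpolation toward the final
measurement), choice bias (+ separate `η_ST`, `η_SA`), and both biases (all
four). Response distributions are predicted by Monte-Carlo simulation
(1,000 precision draws tiled to 4,800 measurement draws, common random
numbers; von Mises deviates via a precomputed inverse-CDF table bilinear in
`(log κ, u)`), and fitted to the 3×3 condensed table (ST / pooled-SA /
no-change) by multinomial maximum likelihood with a generalized pattern
search on the unit cube (initial mesh 0.25 of each range, contraction 0.5,
stop below 1e-3). Because the perceptual and choice biases partially mimic
each other at the ST location, the threshold variants start from three
deterministic initial points seeding both threshold orderings; a fit ending
on a parameter boundary is restarted once from a documented extra initial
condition. Model comparison uses AICc, `−2 logL + 2k + 2k(k+1)/(n−k−1)`, and
leave-session-out cross-validated likelihood (fit on held-in sessions, score
the held-out session, sum folds).

## Inferential statistics

Paired toward-vs-away contrasts use a label-shuffling permutation test
(sign flips of per-participant differences), exhaustive when 2ⁿ ≤ 2¹⁵ and
Monte Carlo with 1,000 draws and add-one smoothing otherwise. Time courses
use a cluster-based permutation test: per-bin one-sample t, cluster-forming
threshold at two-sided α = 0.05, cluster mass = summed t, max-mass null under
participant sign flips. JZS Bayes factors integrate the noncentral-t
likelihood over a Cauchy effect-size prior (scale √2/2 by default,
configurable); the one-tailed variant doubles the half-prior mass. Sequential
analysis recomputes the BF at each cumulative sample size. Holm correction
and Kruskal–Wallis/Wilcoxon/Mann–Whitney delegate to statsmodels/scipy.

Hartigan's dip statistic is computed exactly from its definition — the
minimal sup-distance between the empirical CDF and any unimodal CDF — by
bisection over the distance with a feasibility check built on convex-hull
threading of the CDF constraint bands (mode-knot enumeration with left-limit
and value bands, so atoms at the mode and ties in the data are handled
exactly); the implementation is validated in the test suite against an
independent linear-programming oracle. The p-value bootstraps the dip of
uniform samples of the same size; the pipeline subsamples latency
distributions to 200 points for this test.

## Synthetic-data generator

The generator emulates the task's statistical structure: saccade cue uniform
over four quadrants; change at each location with probability 0.20 or absent
(0.20); post-cue initial-set duration geometric over {10, 30, …, 210} ms
(success probability 0.3, truncated and renormalized — the task design fixes
the support and step, and p = 0.3 concentrates mass at short durations as a
cueing paradigm requires); final set shown 20 ms after a 20 ms blank. Saccade
latencies are ex-Gaussian (μ = 220 ms, σ = 25 ms, τ = 40 ms), chosen to give
a median near 260 ms as observed in this class of task; the latency
distribution family is a modeling choice, as only summaries constrain it.
Wrong-quadrant saccades (7 %) and fixation instability (2 %) are generated as
independent Bernoulli events so the exclusion rules have work to do; trials
whose saccade begins before the final set disappears are excluded, which ties
the inclusion rate to the latency–duration geometry as in the real task
(roughly 75–85 % inclusion).

Detection responses come from a parameterized m-ADC observer (default d′ ≈
1.1, criteria 0.06 toward / 0.24 away, echoing the magnitudes the models are
designed to resolve) or from a VP change observer. Estimation responses come
from a VP observer with condition-dependent mean precision — defaults
`J̄ = (1.3, 6.4, 1.0)`, `τ = 13` — and a recency weight B = 0.5 applied to
initial-set reports at the ST location of double-set trials before encoding
noise. Single-set and noise-mask trials at the ST location use the final-set
precision by default (the presaccadic benefit persists when no second Gabor
follows); the mask is assumed non-interfering. Orientations are i.i.d.
uniform on [0, 180); 60 % of estimation trials are double-set; block-wise
alternation determines the probed set.

What the generator does **not** emulate: oculomotor kinematics beyond
latency/landing summaries, temporal autocorrelation across trials (learning,
fatigue), staircase dynamics (the change angle is a fixed parameter),
response-time structure, and inter-participant heterogeneity beyond what an
observer factory injects. Passing tests therefore establish internal
consistency — that the estimators recover what the generative models encode
at realistic sizes — not that real observers satisfy those models.

## Problem sizes and numerical choices

Recovery and calibration tests run at the sizes a single participant-level
dataset provides (600–3,000 trials, 5–10 synthetic participants, 20–50
replicates); the acceptance script reports each quantity with the size it
was computed at. Monte-Carlo likelihoods use the stated 1,000/4,800 sample
sizes. Probabilities inside multinomial likelihoods are clipped at 1e-12;
degenerate contingency rows warn and fit under constraints; an m-ADC
observer with all thresholds +∞ is admitted as the degenerate always-silent
case. The ±90° orientation tie and the antipodal bias-interpolation tie
resolve deterministically to the +90 branch, which keeps generators
byte-reproducible under a fixed seed.

## Known limitations

- The VP estimation fit pools across participants by design; there is no
  hierarchical per-participant variant.
- The pattern search is derivative-free and deliberately conservative;
  runtime is dominated by the Monte-Carlo likelihood, so sharpening the
  mesh tolerance below 1e-3 buys little.
- The dip statistic's bisection resolves to 1e-6 (1e-5 inside the bootstrap
  loop); samples much larger than a few thousand points make the bootstrap
  slow, hence the pipeline's 200-point subsampling.
- The cluster-permutation test inherits the usual conservativeness of
  max-statistic corrections for small participant counts.
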