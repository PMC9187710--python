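# Methods

## The task and its generative model

A trial of the dynamic clicks task presents two Poisson click trains
whose rates are set by a hidden two-state telegraph process: in the
"go right" state the right speaker clicks at r_hi = 38 Hz and the left
at r_lo = 2 Hz, and vice versa in the "go left" state. The hidden state
switches with hazard h = 1 Hz, the stimulus lasts U(0.5, 2) s, and
reward is baited on the side matching the **final** state. The generator
(`dynclicks.synth`) draws state-change times as exact exponential
inter-event waits (no time binning), then fills each state epoch with
Poisson click counts placed uniformly; the hidden state is frozen at the
go cue. Under these conditions the number of changes per trial is
Poisson mixed over the uniform duration: 31.4% of trials have no change,
33.6% exactly one, 35.0% more than one, and the mean is 1.25 — the
values the task-statistics check reproduces by simulation.

## The accumulation model

The decision variable a integrates clicks with leak, adaptation, and
three noise sources:

    da = (dR(t) C - dL(t) C) dt - lam a dt + sigma_a dW
    dC/dt = (1 - C)/tau_phi,   C -> phi C at each click

Parameters (units, defaults used for the synthetic agent):

| name      | meaning                          | unit   | agent value |
|-----------|----------------------------------|--------|-------------|
| sigma_i2  | initial variance of a0           | a^2    | 0.3         |
| sigma_a2  | memory noise variance            | a^2/s  | 1.0         |
| sigma_s2  | per-click noise variance         | per C  | 1.5         |
| lam       | discounting rate (leaky if < 0)  | 1/s    | -2.0        |
| phi       | adaptation strength              | —      | 0.6         |
| tau_phi   | adaptation recovery              | s      | 0.15        |
| B         | decision boundary / side bias    | a      | 0.1         |
| lapse     | random-choice probability        | —      | 0.05        |

The agent regime is leaky (lam < 0), the optimal qualitative strategy
when the hidden state can change mid-trial. A click's magnitude is the
adaptation state C evaluated immediately before the click (so the first
click always has unit weight); the jump is multiplicative and recovery
exponential, which the implementation evaluates in closed form between
clicks (checked against microscopic ODE integration).

Because the dynamics are affine in a, the distribution of a at any time
is Gaussian with closed-form moments: each click contributes
±C e^{lam (t - s)} to the mean, and sigma_s^2 w(C) e^{2 lam (t - s)} to
the variance, on top of sigma_i^2 e^{2 lam t} and the
Ornstein–Uhlenbeck memory term sigma_a^2 (e^{2 lam t} - 1)/(2 lam).

**Click-noise convention.** The SDE with multiplicative click noise
eta ~ N(1, sigma_s^2) implies per-click variance sigma_s^2 C^2, whereas
the variance recursion we adopt accumulates sigma_s^2 C. The package
defaults to the linear-in-C convention and the simulator draws matching
noise, so analytic moments and Monte-Carlo paths agree by construction;
`ModelParams.click_noise = "quadratic"` switches both consistently.

The probability of a rightward choice is the Gaussian tail mass above B
at the final time, mixed with the lapse: p = (1 - l) Phi((mu - B)/sigma)
+ l/2. Fitting maximizes the Bernoulli likelihood of the observed
choices (bounded L-BFGS-B, optional restarts) with half-Gaussian priors
on sigma_i^2 and sigma_a^2 (scale 30 by default; the scales are
configurable because no canonical values are available). Standard
errors come from the inverse numeric Hessian (central differences) at
the optimum; non-positive-definite directions are reported as NaN.

The SDE simulator used for choices, latent paths, and all Monte-Carlo
oracles steps with the exact Ornstein–Uhlenbeck transition
(decay e^{lam dt}, exact diffusion variance) and applies each click at
its true time decayed to the end of the enclosing 1 ms step, so its
distribution at grid times equals the continuous-time solution at any
step size; there is no Euler discretization bias to tune away.

## The choice-conditioned posterior

The forward density f(a) constrains the initial condition; the backward
distribution b(a) constrains only the final value to the chosen side of
B. b is a mixture over a half-step grid of final values
B ± (j + 1/2) Δa truncated at 12 forward SDs, each component propagated
backward by inverting the affine accumulation map (the adaptation trace
is stimulus-determined and is not inverted): mean
(x_j - S(t)) e^{-lam (tN - t)} and shared variance W(t) e^{-2 lam (tN - t)},
where S and W are the click drift and noise accumulated over (t, tN].
The posterior is the per-time-normalized product f · b on a 1 ms ×
0.1-a grid whose bin edges are anchored at B, so the final slice lies
entirely on the choice side exactly.

Numerical choices:

- Component weights integrate the forward density over each mixture
  cell (a Gaussian CDF difference in final-value space) rather than
  evaluating it at the cell center; this is the exact quadrature of the
  continuum limit and makes refinement second-order.
- The default mixture spacing is 0.05 — half the evaluation bin — the
  coarsest spacing at which halving it again changes any slice's masses
  by < 1e-3 total variation.
- Bin masses are exact Gaussian CDF differences accumulated within an
  8-SD window per component; slices are renormalized, which also
  absorbs the 12-SD truncation.
- Lapse is deliberately not modeled: conditioning assumes a non-lapse
  choice.
- The posterior mean trace needed by the change-of-mind analyses is
  computed directly from the mixture (weights × component means)
  without building the (a, t) grid.

The posterior is validated against rejection sampling: SDE paths kept
when their final value lands on the conditioning side, histogrammed on
the same grid (KL < 0.01 per slice), and by the exact recomposition
P(right) p(a|right) + P(left) p(a|left) = f(a).

## Behavioral assays

- **Ideal observer**: exact discrete-time Bayes filter on the telegraph
  process at 1 ms; each click carries kappa = log(r_hi/r_lo) of
  log-likelihood (the no-click terms cancel because the total click
  rate is state-independent) and the hazard update pulls the log-odds
  toward zero (continuum form da/dt = kappa (dR - dL) - 2h sinh(a)).
  Validated against exhaustive enumeration of state paths on a
  10-bin trial.
- **Psychometric**: 10 quantile bins of the final ideal-observer
  log-odds; Wilson 95% CIs; the model overlay averages the analytic
  choice probability per bin.
- **Chronometric**: accuracy vs final-state duration, grouped by 0 / 1 /
  >1 changes.
- **Reverse correlation**: click trains smoothed with a causal Gaussian
  (SD 5 ms), the state-conditional expected rate difference
  ±(r_hi - r_lo) subtracted using the generative state trajectory,
  averaged by choice on a common 500 ms window before trial end (the
  shortest trial), and normalized to integrate to 1 over that window.

## Neural analyses

Rates: 25 ms bins, causal one-sided Gaussian smoothing (SD 100 ms,
truncated and renormalized so no spike leaks backward in time).
Stimulus-aligned rates are masked after movement, movement-aligned
rates before stimulus onset. Active = mean rate > 1 Hz over [-1 s,
movement]; side-selective = Welch two-tailed t-test (p < 0.05) on
per-trial spike counts in [0, movement] split by choice (the pooled vs
unequal-variance choice is not canonical; Welch is the safer default).
Choice AUC per bin uses midranks (ties count 1/2, degenerate bins 0.5);
permutation p-values are (1 + #{extreme})/(n_perm + 1) with two-tailed
min-tail doubling, 250 permutations; the latency is the first run of 8
consecutive significant bins.

Tuning maps follow the joint-binning construction: each trial's
posterior mass is downsampled into 25 ms × 10 accumulation-value bins
(8 inner bins of width 1.625 symmetric about zero plus two unbounded
tails — both tails are widened since both must capture mass) and paired
with the unit's smoothed rate binned into 100 bins spanning its range;
time slabs are normalized by the number of contributing trials (a slab
contributes only when fully covered by the trial). E[r|a,t], the
residual E[Δr|a,t], and the rank-1 SVD approximation follow, with
f(a) scaled to unit range, m(t) carrying the units, variance explained
s1/Σs, and the sign fixed so f increases toward the unit's preferred
side. For population maps, per-unit z-scored maps (z over all unmasked
stimulus-to-movement bins) are averaged after inverting the a-axis of
left-preferring cells, using only time bins supported by ≥ 10 trials.
Masked cells are zero-filled when they cover < 5% of a map, otherwise
incomplete time rows are dropped before the SVD.

## Change-of-mind analyses

Model-predicted state changes are crossings of B by a centered 100 ms
boxcar running average of the posterior mean; crossings in the first or
last 200 ms are excluded, as are immediately reversed crossings, via
(i) the 100 ms pre/post window means having to sit on the departing and
entering sides of B and (ii) the running-average slope (±10 ms finite
difference) having to match the sign of the entered state. Residual
rates (rate minus the unit's trial-averaged rate per time point) are
realigned to the change time plus a 100 ms response lag, masked beyond
the neighboring changes, averaged by change direction relative to the
unit's preferred state, and scored per bin by d' (count-weighted pooled
SD; 0 when the pooled SD vanishes) with 250-permutation two-tailed
significance. State-change-aligned tuning repeats the joint-binning
construction with time measured from the change, additionally masking
±300 ms around the change where the posterior is too narrow to
estimate tuning.

On synthetic data the population fraction of units discriminating the
two directions dips at the model-predicted change (within the ~3-bin
delay introduced by the causal 100 ms smoother) and later than the
generative change when aligned on generative changes — the ordering
expected when units track the accumulated-evidence sign rather than
the instantaneous stimulus.

## The synthetic population

Spike trains are inhomogeneous Poisson (exact thinning) with rate
max(0, baseline + m(t) f(a(t - lag))), f a sigmoid bounded in
[-0.5, 0.5], m(t) a linear ramp over the first 500 ms that then
plateaus (the shape the population gain analysis should recover), and a
100 ms response lag. The accumulator is taken as 0 before stimulus
onset and frozen at its final value after the go cue. The default mixed
population is 60% tuned (half right-, half left-preferring) and 40%
untuned; recovery checks use homogeneous strongly tuned populations so
the ground truth is unambiguous. A synthetic movement time (go cue +
U(0.1, 0.3) s) stands in for the withdrawal event the neural windows
need. What passing these tests shows is that the estimators recover the
code they assume; real recordings add non-Poisson variability, rate
drift, correlated noise, and tuning heterogeneity that the generator
deliberately omits, so recovery here is a necessary, not sufficient,
check.

## Problem sizes and statistical design of the checks

The test suite runs the oracle comparisons at desk scale: 100k trials
for task statistics; 50 trials × 1e5 paths for the forward-moment
oracle; 1e5-path rejection sampling for the posterior; a 50k-trial fit
for parameter recovery; 360-trial × 8-unit populations for tuning
recovery (posterior slices at 5 ms for map building, which the 25 ms
slabs make equivalent to the 1 ms default); 1000-unit null populations
for calibration; 500 trials × 24 units for change-of-mind ordering.
Where a check aggregates thousands of Monte-Carlo comparisons, the
per-comparison 3 SE level is enforced as a calibration rate together
with the equivalent family-wise bound and an explicit bias test, rather
than as a maximum over all comparisons (which a correct implementation
would fail on the expected extreme).

## Known limitations

- No sticky decision bound, no history effects, no trial-varying
  parameters.
- The posterior conditions on behavior only; neural activity is never
  used to infer the latent.
- The exact forms of the "change strength" exclusion criteria and the
  reverse-correlation alignment window are not canonical for this task
  family; both are configurable, and the defaults are one consistent
  reading.
- Fits on small trial counts (hundreds) leave the noise variances
  weakly identified; the priors keep them bounded but recovery claims
  are made only at the tested scales.
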