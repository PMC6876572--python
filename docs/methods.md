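# Methods

## The two-state occupancy-gated model

A depolymerase hexamer at free concentration c binds the pointed end of a
Cofilin-decorated actin filament as a single-site process: unbound
intervals are exponential with rate λ = k_on·c, bound intervals (dwells)
exponential with rate k_off. The equilibrium occupancy is
cK_A/(1 + cK_A) with K_A = k_on/k_off, computed on demand and never
stored. While a *productive* hexamer is bound, subunits leave as a
Poisson process at v_bound; otherwise at v_unbound. The long-run mean
velocity is therefore

    v̄ = occ·φ·v_bound + (1 − occ·φ)·v_unbound,

with φ the probability that a binding event is depolymerization-competent.
φ defaults to 1 — observed binding events without rapid shortening exist
but their fraction is not quantified, so φ is exposed as a parameter
rather than fixed. Saturation kinetics are described by the
Michaelis–Menten form v = k_cat·c/(K_M + c); the catalytic efficiency
k_cat/K_M equals (subunits removed per binding event) × k_on, so the
processivity per event is (k_cat/K_M)/k_on.

Two deliberate non-reconciliations: the model-implied K_M = k_off/k_on
(≈ 41 nM) and the fitted K_M (≈ 50 nM) are both carried without
adjustment; and fold-changes are reported from unrounded inputs.

## Synthetic data generator

The generator (`capdep.simulate`) is event-driven — exact exponential
sampling of binding/unbinding times, Poisson removal counts per
constant-rate segment with uniformly placed removal times — and only then
discretized to the camera frame grid (0.065 s per frame by default).
There is no fixed-timestep approximation; a fixed seed gives bit-identical
output.

Default study conditions (all overridable): k_on = 1.1 × 10⁷ M⁻¹ s⁻¹,
k_off = 0.45 s⁻¹, c = 83 nM, v_bound = 53 subunits/s (the saturating
k_cat), v_unbound = 0.43 subunits/s (the Cofilin-alone pointed-end rate),
per-site dye probability p = 0.2223 on 6 sites (labeled fraction
f = 1 − (1−p)⁶ = 0.779). Measured filament length carries i.i.d. Gaussian
noise of 10 subunits per frame, standing in for filament Brownian motion
and the sparse (10%) actin labeling; intensity traces carry Gaussian
camera noise and per-dye exponential photobleaching (default
k_bleach = 0.05 s⁻¹ at the end, 0.2 s⁻¹ for surface photobleaching
staircases, which are sampled at SNR = unit step / noise sd = 5).
Subunits leave strictly as monomer-equivalents; oligomeric release,
severing, annealing and re-polymerization are out of scope. Rendered
movies place Gaussian point-spread spots for the ~10% labeled subunits on
a 130 nm (single-molecule) or 143 nm (mf-TIRF) pixel grid with Poisson
shot noise, 2.7 nm of filament length per subunit.

What passing tests on these data do *not* show: robustness to non-Gaussian
length noise (tracking outliers), spatially correlated background, dye
blinking, partial quenching of multi-dye hexamers, or severing — none of
which the generator emulates.

## Trace pipeline and the detector's observation model

Spot intensity is the 5×5 pixel box sum at the tracked pointed end minus
25 × the median of the 72 perimeter pixels of a concentric 19×19 square;
out-of-bounds boxes yield missing values, and up to two consecutive
missing frames inside a run are tolerated. Traces are smoothed with a
0.71 s second-order Savitzky–Golay window (11 frames at 0.065 s). Dwells
are called per trace by a hysteresis threshold — background + 3 robust SD
to enter, +1.5 SD to exit — with background and scale from iterative
sigma clipping seeded by the lowest intensity quartile, so a mostly
occupied trace cannot contaminate the baseline. Because smoothing smears
step edges, run boundaries are refined to the mid-amplitude crossing
(halfway between background and the single-dye level, estimated as the
lower quartile of in-run values so bleaching steps inside a dwell cannot
truncate it), on the raw trace when it is available. Runs are split
wherever ≥2 consecutive raw frames fall below that level. Only runs
strictly longer than 4 frames count as binding events (the cutoff is a
config integer); dwells touching the trace boundaries are censored out,
and gaps are measured between consecutive kept dwells.

These rules define a known observation model with two sharp floors —
a minimum detectable dwell t_d = 4.5 frames and a gap resolution
t_g = 1.5 frames (grid-phase-averaged coverage: an interval of duration d
covers d/Δt frame times on average) — plus two further censoring
mechanisms: unlabeled hexamers (probability 1 − f) and photobleaching of
all dyes during a dwell, after which the remaining bound time is dark.
`capdep.detection_model` computes the predicted observed mean dwell and
mean gap in closed form under this model (zero-truncated binomial dye
counts, per-dye exponential bleaching; the only approximations are that
separations containing a hidden dwell always exceed t_g, and that dark
bleach tails do not merge across t_g — both second-order here).
`estimate_binding_kinetics` inverts the two moment equations for
(k_off, k_on) by root finding on log-rates, with standard errors pushed
through a numerical Jacobian. Simulations at the study conditions confirm
the predicted moments to ~1% and parameter recovery within sampling error;
the naive estimators (1/mean dwell, and the plain labeling correction
m = f·m′ − (1 − f)/k_off followed by k_on = 1/(mc)) are also exposed and
reduce exactly from the generalized forms when the floors and bleaching
are zero. The threshold is per-trace (a global alternative is a config
change); pooling weights each dwell equally, not each filament.

## Photobleaching and the labeling model

Step counting is a penalized least-squares piecewise-constant changepoint
fit (optimal partitioning by an O(n²) vectorized dynamic program — written
directly on numpy), penalty β·σ̂²·log n with σ̂ from the median absolute
first difference /√2, followed by merging of steps smaller than half the
unit intensity; downward level changes are counted. β = 3 and a one-frame
minimum segment were calibrated on synthetic staircases at the design
SNR of 5, where near-coincident bleach events are the dominant error mode
(merging two steps into one biases the labeling fit low); splitting off a
single frame costs two changepoints, so false splits require ~5σ
excursions and are negligible. Traces that do not return to background
are flagged censored and excluded.

The labeling model is a zero-truncated Binomial(6, p) — one cysteine per
protomer, six protomers per hexamer, dark molecules unobservable — fitted
by maximum likelihood; since the printed ±2.6% on the labeled fraction is
not identified as an SE or a CI half-width, the fit reports both a
delta-method SE and a 95% profile-likelihood CI, labelled as such. Equal
unit step heights are assumed (single fluorophore species); blinking and
partial quenching are not modeled.

## Velocimetry and saturation fit

Trajectory velocities are ordinary least-squares slopes of length vs
time (negated so depolymerization is positive; nm inputs divided by
2.7 nm/subunit), with the analytic OLS standard error. Kymograph slopes
use per-row thresholded edge detection and an OLS fit by default
(a least-absolute-deviation option resists edge outliers); the mf-TIRF
frame interval has no default and must be supplied. Segmented
velocimetry fits each bound and unbound interval separately, skipping
and counting intervals shorter than 3 frames. The Michaelis–Menten fit
is unweighted nonlinear least squares (weighted 1/sd² available),
initialized at K_M = median(c), k_cat = max(v), with SEs from the fit
covariance. Velocity histograms are emitted with configurable bins and
are not calibrated against any particular binning.

## Error propagation

Derived quantities (k_cat/K_M and subunits per event) carry first-order
delta-method errors treating the inputs as uncorrelated; a Monte-Carlo
cross-check in the tests shows the expected level of agreement (the ratio
distribution is right-skewed at a 20% CV on K_M, so the first-order SE is
an approximation by construction).

## Problem sizes and orchestration

The analysis scripts and default pipeline use 300 photobleaching
staircases, 8 filaments × 300 s of 83 nM single-molecule imaging
(~450–500 dwells; the printed study pooled 126), 30 filaments per
concentration at 7 concentrations for the saturation series, and 50
trajectories for slope velocimetry — sizes at which every estimator's
sampling error is a few percent and a full run takes seconds. Every
stochastic stage receives a seed derived deterministically from one
master seed; rerunning a stage from saved intermediates is bit-exact,
and the run directory records the effective config and its hash.

## Known limitations

- The merged-event and bleach-tail corrections assume exponential dwells
  and gaps; strongly non-exponential kinetics would bias the inversion.
- Per-trace thresholding needs some unoccupied time in each trace; at
  fully saturating concentrations the background estimate degrades.
- The kymograph edge detector assumes a single filament per kymograph
  and a monotone background-to-filament contrast.
- φ (productive fraction) and bleach-rate heterogeneity between dyes are
  modeled as constants.
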