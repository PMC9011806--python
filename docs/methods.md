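# Methods

This note documents the model, the synthetic stimuli, the numerical
choices and the known limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Efficient allocation of speed tuning curves

A population of `N` Gaussian speed units is allocated to a stimulus
distribution `p(s)` by equal probability mass: with the density model
`d(s) = N p(s)` (its integral equals `N`), the n-th preferred speed is the
`n/N` quantile of the distribution and the width follows the reciprocal of
the local density, `FWHM_n = 1/d(mu_n)`, `sigma_n = FWHM_n/2.355`.  Two
placement conventions are implemented: `literal_eq2` (levels `n/N`,
default), which puts the last peak at the distribution maximum, and
`half_offset` (levels `(n-1/2)/N`), the centered-quantile variant common in
the statistics literature.  The printed-form convention is the default;
the flag exists because the two differ visibly only in the outermost
curves and either convention is defensible.

Distributions are histograms (128 bins by default, spanning `[0, max
observed speed]`).  The CDF is interpolated piecewise-linearly *within*
bins and the density linearly *between bin centers*, so both `mu` and
`sigma` vary continuously as the data drift; a step-function CDF would
make peaks jump between bin edges frame-to-frame and inject artificial
retuning noise.  A zero-width support (all observed speeds identical) is
represented as a point mass and short-circuits to the degenerate path:
every curve collapses onto the single speed with `sigma = 0`, reproducing
the erratic-activity limit rather than raising.  An optional `sigma_floor`
(suggested 0.05 degrees/frame) stabilizes that limit; it is off by
default because the collapse is a behaviour of interest.

Responses are `exp(-(s-mu)^2 / 2 sigma^2)` hard-clipped to zero beyond
`4 sigma` from the peak (keeping >99.99% of the Gaussian mass), matching
the idea that a unit is silent outside its sensitive range.

The *dynamic* variant holds a FIFO buffer of the per-frame speed samples
from the most recent `horizon` frames (10 by default; 333 ms at 30 fps)
and re-derives the tuning every frame from the pooled samples, each vector
weighted equally.  Raw samples rather than per-frame histograms are
buffered so the pooled histogram can be re-binned over the current support
without losing the equal-per-vector weighting.

## Flow synthesis

Stimuli are dense angular flow fields rendered by reprojection: every
pixel of a pinhole camera (90 x 90 degree field of view, square grid) is
back-projected through the scene depth at frame `t` and re-projected
under the pose at `t+1`; flow is the difference of the angular image
coordinates in degrees/frame.  This renders translational *and*
rotational flow exactly, to the precision of the pose chain, and is
validated against an independent scalar-loop oracle at 1e-6 degrees.

Conventions: image origin top-left, row-major; azimuth positive
rightward, elevation positive upward; per-axis exact pinhole mapping
`az = atan(x/f)`.  World frame y-up with the ground at `y = 0`.  The
`.flo` writer converts to pixel units with the single global factor
`fov/grid` recorded in a JSON sidecar.

Three scene families are provided: a bare ground plane (rays above the
horizon miss and are marked invalid "sky"), a frontoparallel wall, and a
*cluttered* scene — a ground plane whose depth is modulated by a smooth
random field under an enclosing dome, so that every ray hits finite
positive depth and the speed histogram is long-tailed the way structured
environments are.  Trial ensembles sample the dome radius log-uniformly
in [8, 60] m, mixing enclosed (warehouse-like) and open (outdoor-like)
environments; without this heterogeneity all trials share nearly the same
speed statistics and a tuning aggregated over the whole set is no longer
a meaningful compromise.

Trajectories follow the multi-segment protocol: start height uniform in
[1, 5] m, five linear segments of 30 frames, each toward a heading pixel
drawn uniformly from the current image at a speed uniform in [1, 20] m/s,
joined by 3-frame transitions (162 frames per trial).  During a
transition the translation direction passes through three interim
headings (spherical interpolation) while the camera re-aims toward the
new heading by a configurable fraction (default 0.5) of the heading
change, which introduces genuine rotational flow — transition frames are
therefore not pure expansion.  Trajectories bringing the camera within
0.5 m of the scene are rejected and re-sampled from a seed offset, an
automated stand-in for manual review.  Optional estimation noise adds
i.i.d. Gaussian perturbations to valid pixels and sparse outlier vectors
(rate 0.02 by default when enabled) to sky pixels, mimicking dense
optical-flow estimators' behaviour in low-contrast regions.

## MT stage

Each grid location hosts a macrocolumn of 24 directions x 7 speeds = 168
units.  Direction tuning is von Mises with concentration `kappa = 10`
(half-height half-width ~21 degrees against the 15-degree spacing);
direction and speed tuning combine multiplicatively — both are free
choices, as no physiological constraint is imposed here, and both are
exposed in the configuration.  Zero-flow and invalid pixels contribute
nothing (their direction is undefined).  Every (direction, speed) channel
is pooled spatially with a normalized Gaussian kernel, `sigma = 1`
grid unit truncated at 4 sigma (9-pixel support; ~3.15 degrees on a
256-pixel 90-degree grid).  Pooling uses zero padding, so channel mass is
conserved for interior structure but decays at the border.

## MSTd stage and decoding

Heading templates tile the field of view on a uniform grid (64 x 64 by
default, ~1.41-degree spacing); each template prefers, at every pixel,
the unit direction pointing away from its focus of expansion.  The
feedforward drive is the rectified cosine alignment between MT direction
channels and the template direction, summed over pixels and over speed
channels — deliberately speed-agnostic, since heading information lives
in the vector directions.  Activity evolves as a leaky integrator with
global subtractive competition,

    a(t+1) = (1 - lambda) a(t) + lambda [drive - g mean(a(t))]_+ ,

and the decoded heading is the preference of the maximally active cell
(ties to the lowest row-major index; an all-zero state yields no heading
signal and the previous estimate is held).  This is a deliberately
simplified stand-in for fully recurrent competitive dynamics with
neighborhood interactions; it reproduces the qualitative behaviour —
estimates depend on the recent time history and track abrupt heading
jumps over many frames — but it should not be mistaken for a complete
competitive-dynamics model with neighborhood kinetics.

The leak was calibrated on the dynamic condition of the desk-scale
stimulus set so that the fitted post-transition convergence takes roughly
10-20 frames, the latency regime of interest; `lambda = 0.05` meets that
band (the integrator's own 98% step response is ~90 frames, but the
winner switch that the error series measures happens much earlier).  The
competition gain is `g = 1`.  Both are configurable.

## Experiments and metrics

The harness renders a seeded trial ensemble once and runs every tuning
condition on identical stimuli: dynamic (horizon 10), static-uniform
(equal-mass allocation to a uniform distribution on [0, 5.3]
degrees/frame) and static-aggregate (allocation to the distribution
pooled over every frame of the ensemble — the pre-pass), plus dynamic
horizons 1 and 30.

Heading error is the 3-D angle between the gaze unit vectors
reconstructed from estimated and true (azimuth, elevation); per-axis
errors are absolute angle differences.  The first segment is excluded
from every aggregate statistic (it starts from empty activity).  Each
analysis window spans a transition plus its following segment; converged
error is the error on the final segment frame, and the error at segment
frame 15 is reported for the early-convergence contrast.  Latency comes
from normalizing each window to 1 at its first frame, fitting a
decreasing 4-parameter logistic by bounded least squares (bounds keep
degenerate segments from poisoning averages; constant series are flagged
and excluded), averaging parameters across windows, and solving in closed
form for the frame at which the averaged curve has dropped by 98% of its
range.  Condition contrasts use percentile bootstrap CIs (2000 resamples)
and a one-sided paired bootstrap p-value instead of repeated-measures
ANOVA: the inference machinery is reporting apparatus, not the model.

Desk-scale defaults are 10 trials with 32 x 32 MT and MSTd grids, which
keeps a full two-experiment reproduction to a few minutes on one CPU;
the grids, trial count and noise level are ordinary parameters for
larger-fidelity runs.

## What the generator does and does not emulate

The synthetic ensemble reproduces the stimulus *protocol* (field of view,
trajectory structure, speed and height ranges, heterogeneous depth
statistics) but not photorealistic content or estimator artifacts: flow
is exact reprojection, optionally with additive Gaussian noise, not the
output of a pyramidal estimator on rendered video.  Consequently the
experiments reproduce the qualitative contrasts — dynamic tuning beats
the static uniform tuning decisively in both converged error and latency,
transition frames show an error spike in every condition, and the dynamic
horizon has little effect between 1 and 30 frames — but not absolute
error magnitudes from richer models, and the static-aggregate control lands statistically
*indistinguishable from* (numerically slightly below) dynamic tuning
rather than clearly above it.  A memoryless probe (leak 1, no
competition) shows why: on noiseless synthetic flow all three tunings
yield the same feedforward decode bias (~1.4 degrees at these grids), so
the aggregate control has full per-segment coverage and there is nothing
left for adaptation to win; on real, estimator-derived video an
aggregate control is typically a poorer per-segment match and richer
recurrent dynamics can amplify coverage differences; both effects are
outside this package's scope.
Passing tests therefore certify the allocation mathematics, the geometry,
the dynamics and the dynamic-vs-uniform contrast — not effect sizes on
real video.

## Degenerate inputs and edge cases

* All-zero flow: a valid point-mass distribution at 0; MT activity is
  zero, the MSTd state carries no signal, the previous decode is held.
* Point-mass distributions: collapsed tuning, flagged; with the sigma
  floor enabled, curves respond in a narrow band instead.  At desk scale
  a true collapse requires every pooled magnitude to be bit-identical,
  which rendered scenes essentially never produce, so horizon-1 runs log
  zero degenerate frames.
* Zero first-frame error in a window: normalization undefined; the
  window is skipped with a logged warning.
* Ties in the decode: resolved to the lowest row-major index,
  deterministically.

## Reproducibility

Every stage derives its randomness from a master seed through counter-
based `SeedSequence` children (`stage_seed`), so stages can be re-run in
isolation; a fixed seed yields byte-identical CSV/JSON outputs.  Resolved
configurations are serialized (YAML) alongside outputs.
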