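# dese — dynamic efficient sensory encoding of optic flow

`dese` is a computational-neuroscience toolkit for studying **adaptive
speed tuning** in neural models of visual motion processing.  It asks a
simple question: if a small population of speed-tuned units (model area MT)
continually re-derives its Gaussian tuning curves from the distribution of
optic-flow speeds it has *just seen*, does a downstream heading decoder
(model area MSTd) get better?  The package provides

* the efficient-coding allocation of `N` Gaussian speed curves to a
  stimulus distribution, and its *dynamic* rolling-horizon variant,
* a seeded ego-motion generator producing ground-truth dense optic flow
  from parametric 3-D scenes and multi-segment camera trajectories,
* a two-stage MT → MSTd heading model (joint direction x speed
  macrocolumns, radial-expansion templates, leaky competitive dynamics),
* an experiment harness comparing dynamic against static tunings with
  heading-error and logistic-latency metrics,
* a CLI (`dese generate / tune / simulate / analyze / reproduce`) and
  Middlebury `.flo` readers/writers.

It is aimed at modelers of the primate dorsal stream and at anyone who
needs a principled, parameter-free way to keep a simulated population
sensitive to a drifting stimulus distribution.

## The allocation rule

Given a probability distribution `p(s)` of stimulus speeds and `N` neurons,
define the density model

    d(s) = N p(s)

so that the integral of `d` equals `N`.  The preferred speed of the n-th
unit is placed where the cumulative density reaches `n`,

    mu_n = s_n  where  D(s_n) = n,

i.e. at the `n/N` quantile: every unit captures an equal share of the
probability mass.  The tuning width is set by the local density,

    FWHM_n = 1 / d(s_n),     sigma_n = FWHM_n / 2.355,

so curves are narrow and dense where speeds are common, broad and sparse
where they are rare.  *Dynamic* efficient sensory encoding repeats this
derivation every frame on the histogram of flow magnitudes pooled over a
rolling horizon of the most recent `n` frames (10 frames = 333 ms at
30 fps by default), with every stored vector weighted equally.

## Worked example

```python
import numpy as np
from dese import EfficientSpeedEncoder, SpeedDistribution

# seven units allocated to a uniform speed distribution on [0, 50]
enc = EfficientSpeedEncoder(n_neurons=7).fit(
    SpeedDistribution.uniform(0.0, 50.0, bins=500))
print(np.round(enc.mu_, 4))
print(np.round(enc.sigma_, 4))
```

prints

```
[ 7.1429 14.2857 21.4286 28.5714 35.7143 42.8571 50.    ]
[3.0331 3.0331 3.0331 3.0331 3.0331 3.0331 3.0331]
```

— the peaks sit at the quantiles `50 n / 7` and every curve has
`FWHM = 50/7`, hence `sigma = 50/7/2.355 ≈ 3.03` degrees/frame.  For a
non-uniform distribution the peaks crowd into the body and the widths
shrink there by exactly the inverse of the local density.

Running the scaled-down tuning-condition comparison from the shell:

```bash
dese reproduce --seed 0 --trials 10 --out-dir runs/demo
```

writes per-trial error CSVs and a `summary.json`/`summary.csv`; at seed 0
the summary table reads (10 trials, 32 x 32 grids, values in degrees and
frames):

```
condition         converged_error_deg  convergence_frame
dynamic_h10                     2.79               14.3
static_uniform                  4.31               16.4
static_aggregate                2.15               19.2
dynamic_h1                      3.06               15.5
dynamic_h30                     2.32               16.9
```

Dynamic tuning clearly beats the static uniform tuning (its converged
error is ~35% lower and its latency shortest), while the static tuning
aggregated over the whole stimulus set is statistically indistinguishable
from dynamic tuning on this synthetic ensemble; varying the dynamic
horizon between 1 and 30 frames has little effect.  See
`docs/methods.md` for what this generator does and does not emulate.

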