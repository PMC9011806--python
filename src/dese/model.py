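"""Two-stage MT -> MSTd heading model with pluggable speed tuning.

:class:`OpticFlowHeadingModel` wires the pieces together: a speed tuning
policy (dynamic rolling-horizon re-derivation, a static uniform-range
tuning, or a static tuning aggregated over a stimulus set), the MT
macrocolumn grid, the MSTd radial-template bank with recurrent competition,
and the argmax heading decode.  ``predict`` consumes a flow sequence (one
trial) and returns per-frame heading estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .encoding import (RollingHorizon, SpeedDistribution,
                       build_speed_distribution, derive_tuning)
from .mstd import (MSTdState, NoHeadingSignalError, TemplateBank,
                   decode_heading, recurrent_step)
from .mt import MTPopulation

TUNING_MODES = ("dynamic", "static_uniform", "static_aggregate", "fixed")


class OpticFlowHeadingModel(BaseEstimator):
    """Heading-from-optic-flow estimator with dynamic or static speed tuning.

    Parameters
    ----------
    tuning_mode : {'dynamic', 'static_uniform', 'static_aggregate', 'fixed'}
        Dynamic re-derives the speed tuning every frame from the rolling
        horizon; static_uniform derives it once from a uniform distribution
        on ``static_uniform_range``; static_aggregate derives it from the
        whole stimulus set given to ``fit``; fixed uses ``tuning`` as given.
    horizon : int, default 10
        Rolling time horizon in frames (dynamic mode; 10 frames = 333 ms at
        30 fps).
    static_uniform_range : tuple, default (0.0, 5.3)
        Degrees/frame span of the uniform static tuning.
    n_speeds, n_directions, pooling_sigma, kappa : MT parameters.
    mstd_grid : int, default 64
        Template-bank side; heading resolution is fov/mstd_grid degrees.
    leak, inhibition : recurrent dynamics parameters (lambda and the global
        competition gain).
    bins : int, default 128
        Histogram resolution for derived distributions.
    placement : {'literal_eq2', 'half_offset'}
        Quantile-level convention for peak placement.
    sigma_floor : float or None
        Optional sigma floor guarding the collapsed-tuning limit.
    template_bank : TemplateBank or None
        Optionally share a precomputed bank between model instances.
    """

    def __init__(self, tuning_mode: str = "dynamic", horizon: int = 10,
                 static_uniform_range: tuple = (0.0, 5.3),
                 n_speeds: int = 7, n_directions: int = 24,
                 pooling_sigma: float = 1.0, kappa: float = 10.0,
                 mstd_grid: int = 64, fov_deg: float = 90.0,
                 leak: float = 0.05, inhibition: float = 1.0,
                 bins: int = 128, placement: str = "literal_eq2",
                 sigma_floor: float | None = None, cutoff: float = 4.0,
                 tuning=None, template_bank: TemplateBank | None = None):
        self.tuning_mode = tuning_mode
        self.horizon = horizon
        self.static_uniform_range = static_uniform_range
        self.n_speeds = n_speeds
        self.n_directions = n_directions
        self.pooling_sigma = pooling_sigma
        self.kappa = kappa
        self.mstd_grid = mstd_grid
        self.fov_deg = fov_deg
        self.leak = leak
        self.inhibition = inhibition
        self.bins = bins
        self.placement = placement
        self.sigma_floor = sigma_floor
        self.cutoff = cutoff
        self.tuning = tuning
        self.template_bank = template_bank

    # -- fitting ---------------------------------------------------------

    def fit(self, X=None, y=None):
        """Resolve the static tuning where one is required.

        ``X`` is a sequence of trials (each a sequence of flow fields) or a
        :class:`SpeedDistribution`; it is only consulted in
        ``static_aggregate`` mode, where the tuning is derived from the
        distribution pooled over every frame of the whole set (the pre-pass).
        """
        if self.tuning_mode not in TUNING_MODES:
            raise ValueError(f"unknown tuning_mode {self.tuning_mode!r}")
        if self.tuning_mode == "static_uniform":
            lo, hi = self.static_uniform_range
            dist = SpeedDistribution.uniform(lo, hi, self.bins)
            self.tuning_ = derive_tuning(dist, self.n_speeds, self.placement,
                                         self.sigma_floor, "static_uniform")
        elif self.tuning_mode == "static_aggregate":
            if isinstance(X, SpeedDistribution):
                dist = X
            else:
                if X is None:
                    raise ValueError("static_aggregate requires a stimulus pre-pass")
                flows = [f for trial in X for f in trial]
                dist = build_speed_distribution(flows, bins=self.bins)
            self.aggregate_distribution_ = dist
            self.tuning_ = derive_tuning(dist, self.n_speeds, self.placement,
                                         self.sigma_floor, "static_aggregate")
        elif self.tuning_mode == "fixed":
            if self.tuning is None:
                raise ValueError("fixed mode requires an explicit tuning")
            self.tuning_ = self.tuning
        else:  # dynamic
            self.tuning_ = None
        return self

    # -- prediction -------------------------------------------------------

    def _bank(self, mt_grid: int) -> TemplateBank:
        bank = self.template_bank
        if (bank is None or bank.mt_grid != mt_grid
                or bank.grid != self.mstd_grid
                or bank.n_directions != self.n_directions):
            bank = TemplateBank(self.mstd_grid, self.fov_deg, mt_grid,
                                self.n_directions)
            self.template_bank = bank
        return bank

    def predict(self, frames) -> pd.DataFrame:
        """Run one trial and decode a heading per frame.

        Returns a DataFrame with columns ``frame, azimuth, elevation,
        margin, degenerate, held``; ``held`` marks frames on which the
        activity carried no heading signal and the previous estimate was
        retained.  Recurrent state and the rolling horizon start empty for
        every call: trials are independent.
        """
        if not hasattr(self, "tuning_"):
            self.fit()
        frames = list(frames)
        if not frames:
            raise ValueError("no flow data")
        grid = frames[0].grid
        bank = self._bank(grid)
        mt = MTPopulation(grid=grid, n_directions=self.n_directions,
                          n_speeds=self.n_speeds, pooling_sigma=self.pooling_sigma,
                          kappa=self.kappa, cutoff=self.cutoff, tuning=self.tuning_)
        hor = (RollingHorizon(self.horizon, self.bins)
               if self.tuning_mode == "dynamic" else None)
        state = MSTdState.zeros(self.mstd_grid, leak=self.leak)
        prev = None
        rows = []
        for i, f in enumerate(frames):
            if hor is not None:
                dist = hor.update(f)
                tuning = derive_tuning(dist, self.n_speeds, self.placement,
                                       self.sigma_floor, "dynamic", self.horizon)
                mt.retune(tuning)
            act = mt.transform(f)
            drive = bank.match(act)
            state = recurrent_step(state, drive, inhibition=self.inhibition)
            held = False
            try:
                est = decode_heading(state, bank)
                prev = est
            except NoHeadingSignalError:
                held = True
                est = prev  # default policy: hold the previous estimate
            rows.append({
                "frame": i,
                "azimuth": est.azimuth if est is not None else 0.0,
                "elevation": est.elevation if est is not None else 0.0,
                "margin": est.margin if est is not None else 0.0,
                "degenerate": bool(mt.tuning.degenerate) if mt.tuning else False,
                "held": held,
            })
        return pd.DataFrame(rows)
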