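"""Model area MT: macrocolumns with joint direction x speed tuning.

Every grid location hosts an identical macrocolumn of units covering all
combinations of ``n_directions`` preferred directions (von Mises tuned) and
``n_speeds`` Gaussian speed curves, 24 x 7 = 168 units at defaults.  The
per-pixel response is the product of direction and speed tuning; each
(direction, speed) channel is then pooled spatially with a normalized
Gaussian kernel (sigma 1.0 grid units, truncated at 4 sigma, i.e. a
9-pixel support).

The speed curves are pluggable: :meth:`MTPopulation.retune` swaps in a new
tuning set, and the speed-channel index always denotes rank order (slowest
to fastest), never an absolute speed.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import TuningCurveSet


class MTPopulation(TransformerMixin, BaseEstimator):
    """Grid of MT macrocolumns as a flow-field -> activity transformer.

    Parameters
    ----------
    grid : int, default 256
        Side of the square macrocolumn grid; must match the flow grid.
    n_directions : int, default 24
        Preferred directions, evenly spaced 360/n degrees apart.
    n_speeds : int, default 7
        Speed channels; the attached tuning set must have this many curves.
    pooling_sigma : float, default 1.0
        Gaussian spatial pooling sigma in grid units.
    kappa : float, default 10.0
        Von Mises concentration of the direction curves.  The direction
        bandwidth is not constrained by physiology here; kappa ~= 10 gives a
        half-height half-width of ~21 degrees against the 15-degree spacing.
    cutoff : float, default 4.0
        Speed responses are clipped to zero beyond ``cutoff`` sigmas.
    tuning : TuningCurveSet or None
        Initial speed tuning; may also be set later via :meth:`retune`.
    """

    def __init__(self, grid: int = 256, n_directions: int = 24, n_speeds: int = 7,
                 pooling_sigma: float = 1.0, kappa: float = 10.0,
                 cutoff: float = 4.0, tuning: TuningCurveSet | None = None):
        self.grid = grid
        self.n_directions = n_directions
        self.n_speeds = n_speeds
        self.pooling_sigma = pooling_sigma
        self.kappa = kappa
        self.cutoff = cutoff
        self.tuning = tuning

    # -- tuning management ----------------------------------------------

    @property
    def macrocolumn_size(self) -> int:
        return self.n_directions * self.n_speeds

    @property
    def preferred_directions_deg(self) -> np.ndarray:
        return np.arange(self.n_directions) * 360.0 / self.n_directions

    def _check_tuning(self, tuning: TuningCurveSet) -> TuningCurveSet:
        if tuning is None:
            raise ValueError("MTPopulation has no speed tuning attached")
        if len(tuning) != self.n_speeds:
            raise ValueError(
                f"tuning has {len(tuning)} curves, expected {self.n_speeds}"
            )
        return tuning

    def retune(self, new_tuning: TuningCurveSet) -> "MTPopulation":
        """Swap in a new speed tuning set; subsequent responses use it."""
        self.tuning = self._check_tuning(new_tuning)
        return self

    # -- response --------------------------------------------------------

    def fit(self, X=None, y=None):
        # stateless apart from the tuning attached at construction/retune
        self._check_tuning(self.tuning)
        return self

    def transform(self, flow, tuning: TuningCurveSet | None = None) -> np.ndarray:
        """Respond to one flow field: activity of shape (grid, grid, D, S).

        Invalid and zero-flow pixels contribute nothing (direction is
        undefined there), then every channel is pooled spatially.
        """
        t = self._check_tuning(tuning if tuning is not None else self.tuning)
        u, v, valid = self._unpack(flow)
        if u.shape != (self.grid, self.grid):
            raise ValueError(
                f"flow grid {u.shape} does not match MT grid {self.grid}"
            )
        speed = np.hypot(u, v)
        theta = np.arctan2(v, u)
        prefs = np.radians(self.preferred_directions_deg)
        dir_act = np.exp(self.kappa * (np.cos(theta[..., None] - prefs) - 1.0))
        speed_act = t.response(speed, cutoff=self.cutoff)
        act = dir_act[..., :, None] * speed_act[..., None, :]
        act[(speed == 0) | ~valid] = 0.0
        if self.pooling_sigma > 0:
            act = gaussian_filter(act, sigma=self.pooling_sigma, truncate=4.0,
                                  mode="constant", axes=(0, 1))
        return act

    @staticmethod
    def _unpack(flow):
        if hasattr(flow, "u"):
            return flow.u, flow.v, flow.valid
        u, v = flow
        return np.asarray(u, float), np.asarray(v, float), np.ones(np.shape(u), bool)


def pooling_kernel(sigma: float = 1.0, truncate: float = 4.0) -> np.ndarray:
    """The normalized spatial pooling kernel (9 x 9 support at defaults)."""
    r = int(truncate * sigma + 0.5)
    n = 2 * r + 1
    impulse = np.zeros((n, n))
    impulse[r, r] = 1.0
    return gaussian_filter(impulse, sigma=sigma, truncate=truncate, mode="constant")
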