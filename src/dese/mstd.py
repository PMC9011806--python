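"""Model area MSTd: radial templates, recurrent competition, heading decode.

A 64 x 64 bank (at defaults) of template cells spans the field of view, each
tuned to a radially expanding flow pattern centered on its focus of
expansion.  A template's feedforward drive is the rectified-cosine match
between MT direction channels and the template's radial direction at every
pixel, summed over speed channels — the match is carried by vector
directions, deliberately speed-agnostic.  Activity then evolves with a
leaky integrator under global competition,

    a(t+1) = (1 - lambda) a(t) + lambda [drive - g * mean(a(t))]_+ ,

a simplified stand-in for fully recurrent competitive population dynamics:
heading estimates depend on the recent time history, so abrupt heading jumps
are tracked over multiple frames rather than instantly.  The decoded heading
is the preference of the maximally active cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: precompute the full (directions, templates, pixels) weight tensor
#: only below this size (bytes); larger banks stream per direction.
_PRECOMPUTE_LIMIT_BYTES = 512 * 2**20


class NoHeadingSignalError(RuntimeError):
    """Raised when a heading is requested from an all-zero activity state."""


@dataclass(frozen=True)
class HeadingEstimate:
    """Decoded heading: angles from the image center plus the winning cell."""

    azimuth: float
    elevation: float
    index: tuple
    margin: float


class TemplateBank:
    """Radial-expansion templates on a uniform grid of FoE positions.

    FoE positions are cell centers of a uniform ``grid x grid`` partition of
    the angular field of view, so adjacent headings differ by ``fov/grid``
    degrees (~1.41 at 90/64).  The template's preferred direction at a pixel
    is the unit vector pointing away from its FoE in angular coordinates.
    """

    def __init__(self, grid: int = 64, fov_deg: float = 90.0,
                 mt_grid: int = 256, n_directions: int = 24):
        self.grid = int(grid)
        self.fov_deg = float(fov_deg)
        self.mt_grid = int(mt_grid)
        self.n_directions = int(n_directions)

        step = self.fov_deg / self.grid
        self.spacing_deg = step
        self.az_centers = -self.fov_deg / 2 + step * (np.arange(self.grid) + 0.5)
        self.el_centers = (self.fov_deg / 2 - step * (np.arange(self.grid) + 0.5))

        # MT pixel angular coordinates (same mapping as the camera model)
        t = math.tan(math.radians(self.fov_deg / 2))
        px = -t + 2 * t / self.mt_grid * (np.arange(self.mt_grid) + 0.5)
        az_pix = np.degrees(np.arctan(px))
        el_pix = np.degrees(np.arctan(t - 2 * t / self.mt_grid
                                      * (np.arange(self.mt_grid) + 0.5)))
        AZ, EL = np.meshgrid(az_pix, el_pix)
        self._az_pix = AZ.ravel()
        self._el_pix = EL.ravel()

        foe_az = np.repeat(self.az_centers[None, :], self.grid, axis=0).ravel()
        foe_el = np.repeat(self.el_centers[:, None], self.grid, axis=1).ravel()
        daz = self._az_pix[None, :] - foe_az[:, None]
        del_ = self._el_pix[None, :] - foe_el[:, None]
        r = np.hypot(daz, del_)
        rs = np.where(r > 0, r, 1.0)
        self._cos = np.where(r > 0, daz / rs, 0.0).astype(np.float32)
        self._sin = np.where(r > 0, del_ / rs, 0.0).astype(np.float32)

        self.n_templates = self.grid * self.grid
        n_pix = self.mt_grid * self.mt_grid
        bytes_needed = 4 * self.n_directions * self.n_templates * n_pix
        self._w = None
        if bytes_needed <= _PRECOMPUTE_LIMIT_BYTES:
            prefs = np.radians(np.arange(self.n_directions) * 360.0 / self.n_directions)
            w = (np.cos(prefs)[:, None, None] * self._cos[None]
                 + np.sin(prefs)[:, None, None] * self._sin[None])
            np.maximum(w, 0.0, out=w)
            self._w = w.astype(np.float32)

    def heading_of(self, i: int, j: int) -> tuple:
        """(azimuth, elevation) preference of grid cell (row i, col j)."""
        return float(self.az_centers[j]), float(self.el_centers[i])

    def match(self, mt_activity: np.ndarray) -> np.ndarray:
        """Feedforward drive of every template, shape (grid, grid).

        ``mt_activity`` is the (G, G, D, S) MT response; speed channels are
        summed before matching and negative direction alignments are
        rectified to zero.
        """
        G = mt_activity.shape[0]
        if G != self.mt_grid or mt_activity.shape[1] != self.mt_grid:
            raise ValueError("MT grid does not match the template bank")
        if mt_activity.shape[2] != self.n_directions:
            raise ValueError("direction channels do not match the template bank")
        A = mt_activity.sum(axis=3).reshape(-1, self.n_directions).astype(np.float32)
        drive = np.zeros(self.n_templates, dtype=np.float64)
        prefs = np.radians(np.arange(self.n_directions) * 360.0 / self.n_directions)
        if self._w is not None:
            for d in range(self.n_directions):
                drive += self._w[d] @ A[:, d]
        else:
            for d in range(self.n_directions):
                w = math.cos(prefs[d]) * self._cos + math.sin(prefs[d]) * self._sin
                np.maximum(w, 0.0, out=w)
                drive += w @ A[:, d]
        return drive.reshape(self.grid, self.grid)


def feedforward_match(mt_activity: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Functional alias for :meth:`TemplateBank.match`."""
    return bank.match(mt_activity)


@dataclass
class MSTdState:
    """Recurrent template-cell activity with leak rate lambda in (0, 1]."""

    activity: np.ndarray
    leak: float = 0.2
    frame: int = 0

    def __post_init__(self):
        if not 0.0 < self.leak <= 1.0:
            raise ValueError("leak rate must lie in (0, 1]")
        if np.any(self.activity < 0) or not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite and non-negative")

    @classmethod
    def zeros(cls, grid: int, leak: float = 0.2) -> "MSTdState":
        return cls(np.zeros((grid, grid)), leak=leak, frame=0)


def recurrent_step(state: MSTdState, drive: np.ndarray,
                   inhibition: float = 1.0) -> MSTdState:
    """One step of the leaky-integrator competition dynamics.

    With leak 1 and zero inhibition the state equals the instantaneous
    drive (memoryless limit); smaller leaks blend in the previous state so
    heading transitions play out over multiple frames.
    """
    if np.any(drive < 0):
        raise ValueError("drive must be non-negative")
    lam = state.leak
    inhib = inhibition * float(np.mean(state.activity))
    a = (1.0 - lam) * state.activity + lam * np.maximum(drive - inhib, 0.0)
    return MSTdState(a, leak=lam, frame=state.frame + 1)


def decode_heading(state: MSTdState | np.ndarray, bank: TemplateBank) -> HeadingEstimate:
    """Heading preference of the maximally active cell.

    Ties break toward the lowest row-major index; an all-zero state carries
    no heading signal and raises (callers usually hold the previous
    estimate).
    """
    act = state.activity if isinstance(state, MSTdState) else np.asarray(state)
    if act.shape != (bank.grid, bank.grid):
        raise ValueError("state grid does not match the template bank")
    if not np.any(act > 0):
        raise NoHeadingSignalError("no heading signal")
    flat = int(np.argmax(act))  # argmax takes the first (lowest row-major) max
    i, j = divmod(flat, bank.grid)
    az, el = bank.heading_of(i, j)
    top = float(act.flat[flat])
    rest = np.delete(act.ravel(), flat)
    margin = top - float(rest.max()) if rest.size else top
    return HeadingEstimate(az, el, (i, j), margin)
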