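"""Efficient sensory encoding of optic-flow speed.

A population of N speed-tuned units is allocated to a stimulus distribution
p(s) so that each unit captures an equal share of the probability mass:
the density model is d(s) = N p(s); the n-th preferred speed mu_n is placed
where the cumulative density D reaches level n; the tuning width is set by
the local density, FWHM_n = 1 / d(mu_n), and sigma_n = FWHM_n / 2.355 for
Gaussian curves.  Dense, narrow curves therefore cover common speeds and
sparse, broad curves cover rare ones.

The *dynamic* variant re-derives this allocation every frame from the
distribution of flow magnitudes pooled over a rolling horizon of the most
recent frames, so the population tracks the statistics of the stimulus as
the observer moves.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: Ratio between the full width at half maximum and the standard deviation
#: of a Gaussian (2*sqrt(2*ln 2), printed to the precision used throughout).
FWHM_OVER_SIGMA = 2.355

_MASS_TOL = 1e-9


class NoFlowDataError(ValueError):
    """Raised when a speed distribution is requested from empty input."""


@dataclass(frozen=True)
class SpeedDistribution:
    """Empirical distribution of optic-flow speeds (degrees/frame).

    Histogram with strictly increasing ``bin_edges`` and per-bin probability
    ``bin_mass``.  The CDF is interpolated piecewise-linearly within bins so
    quantiles vary continuously with the data.  An all-identical sample is
    represented as a point mass (zero-width support, single bin).
    """

    bin_edges: np.ndarray
    bin_mass: np.ndarray
    n_samples: int

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        mass = np.asarray(self.bin_mass, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "bin_mass", mass)
        if self.n_samples < 1:
            raise NoFlowDataError("no flow data")
        if edges.ndim != 1 or mass.ndim != 1 or edges.size != mass.size + 1:
            raise ValueError("bin_edges must have one more entry than bin_mass")
        if np.any(mass < -_MASS_TOL):
            raise ValueError("bin_mass entries must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-9:
            raise ValueError("bin_mass must sum to 1")
        if self.is_point_mass:
            return
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")

    # -- construction ---------------------------------------------------

    @classmethod
    def from_samples(cls, speeds, bins: int = 128) -> "SpeedDistribution":
        """Histogram speed samples over [0, max observed speed]."""
        speeds = np.asarray(speeds, dtype=float).ravel()
        if speeds.size == 0:
            raise NoFlowDataError("no flow data")
        if np.any(speeds < 0):
            raise ValueError("speeds must be non-negative")
        if bins < 2:
            raise ValueError("bins must be >= 2")
        lo, hi = float(speeds.min()), float(speeds.max())
        if hi == lo:
            # zero-width support: point mass, degenerate downstream
            return cls(np.array([hi, hi]), np.array([1.0]), speeds.size)
        counts, edges = np.histogram(speeds, bins=bins, range=(0.0, hi))
        return cls(edges, counts / speeds.size, speeds.size)

    @classmethod
    def uniform(cls, low: float, high: float, bins: int = 128) -> "SpeedDistribution":
        """Analytic uniform distribution on [low, high] (e.g. 0-5.3 deg/frame)."""
        if not high > low >= 0:
            raise ValueError("need high > low >= 0")
        edges = np.linspace(low, high, bins + 1)
        return cls(edges, np.full(bins, 1.0 / bins), n_samples=1)

    # -- queries ---------------------------------------------------------

    @property
    def is_point_mass(self) -> bool:
        return self.bin_edges[0] == self.bin_edges[-1]

    @property
    def support(self) -> tuple[float, float]:
        return float(self.bin_edges[0]), float(self.bin_edges[-1])

    @property
    def _cum(self) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(self.bin_mass)])
        c[-1] = 1.0
        return c

    def cdf(self, s) -> np.ndarray:
        """Piecewise-linear CDF evaluated at speed(s) ``s``."""
        if self.is_point_mass:
            return np.where(np.asarray(s, float) >= self.bin_edges[0], 1.0, 0.0)
        return np.interp(np.asarray(s, float), self.bin_edges, self._cum)

    def quantile(self, q) -> np.ndarray:
        """Generalized inverse of the piecewise-linear CDF.

        For levels falling inside a zero-mass bin the lowest speed attaining
        the level is returned.
        """
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        if self.is_point_mass:
            return np.full_like(q, self.bin_edges[0])
        cum = self._cum
        idx = np.clip(np.searchsorted(cum, q, side="left"), 1, len(cum) - 1)
        dm = cum[idx] - cum[idx - 1]
        frac = np.where(dm > 0, (q - cum[idx - 1]) / np.where(dm > 0, dm, 1.0), 0.0)
        out = self.bin_edges[idx - 1] + frac * np.diff(self.bin_edges)[idx - 1]
        return np.where(q <= 0, self.bin_edges[0], out)

    def pdf(self, s) -> np.ndarray:
        """Probability density at ``s``, linearly interpolated between bin centers."""
        if self.is_point_mass:
            raise ValueError("density of a point mass is undefined")
        widths = np.diff(self.bin_edges)
        dens = self.bin_mass / widths
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return np.interp(np.asarray(s, float), centers, dens,
                         left=dens[0], right=dens[-1])

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges.tolist(),
            "bin_mass": self.bin_mass.tolist(),
            "n_samples": int(self.n_samples),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpeedDistribution":
        return cls(np.asarray(d["bin_edges"]), np.asarray(d["bin_mass"]),
                   int(d["n_samples"]))


@dataclass(frozen=True)
class DensityModel:
    """Neural density d(s) = N p(s); its integral over the support equals N."""

    n_neurons: int
    source: SpeedDistribution

    def density(self, s) -> np.ndarray:
        return self.n_neurons * self.source.pdf(s)

    def cumulative(self, s) -> np.ndarray:
        """Cumulative density D(s); preferred speeds solve D(s_n) = n."""
        return self.n_neurons * self.source.cdf(s)

    def integral(self) -> float:
        widths = np.diff(self.source.bin_edges)
        return float(self.n_neurons * np.sum(self.source.bin_mass / widths * widths))


@dataclass(frozen=True)
class TuningCurve:
    """One Gaussian speed curve: peak ``mu``, width ``fwhm``, ``sigma`` = fwhm/2.355."""

    index: int
    mu: float
    fwhm: float
    sigma: float
    degenerate: bool = False

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not self.degenerate:
            if self.fwhm <= 0:
                raise ValueError("fwhm must be positive for non-degenerate curves")
            if abs(self.sigma - self.fwhm / FWHM_OVER_SIGMA) > 1e-9 * max(1.0, self.sigma):
                raise ValueError("sigma must equal fwhm / 2.355")


@dataclass(frozen=True)
class TuningCurveSet:
    """Ordered set of N Gaussian speed curves plus provenance metadata.

    ``provenance`` is one of ``static_uniform``, ``static_aggregate`` or
    ``dynamic`` (with ``horizon`` frames in the dynamic case); the channel
    index is a rank (slowest to fastest), never an absolute speed.
    """

    curves: tuple
    provenance: str = "static_uniform"
    horizon: int | None = None

    def __post_init__(self):
        mus = self.mu
        if np.any(np.diff(mus) < -1e-12):
            raise ValueError("preferred speeds must be non-decreasing in index")

    def __len__(self) -> int:
        return len(self.curves)

    @property
    def mu(self) -> np.ndarray:
        return np.array([c.mu for c in self.curves])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([c.sigma for c in self.curves])

    @property
    def fwhm(self) -> np.ndarray:
        return np.array([c.fwhm for c in self.curves])

    @property
    def degenerate(self) -> bool:
        return any(c.degenerate for c in self.curves)

    def response(self, speeds, cutoff: float = 4.0) -> np.ndarray:
        """Population response to ``speeds``; shape ``speeds.shape + (N,)``."""
        speeds = np.asarray(speeds, dtype=float)
        if np.any(speeds < 0):
            raise ValueError("speed must be non-negative")
        mu = self.mu
        sigma = self.sigma
        d = speeds[..., None] - mu
        out = np.zeros(d.shape)
        ok = sigma > 0
        if np.any(ok):
            z = d[..., ok] / sigma[ok]
            out[..., ok] = np.where(np.abs(z) <= cutoff, np.exp(-0.5 * z * z), 0.0)
        if np.any(~ok):
            # collapsed curve: responds only to an exact match with its peak
            out[..., ~ok] = (d[..., ~ok] == 0).astype(float)
        return out

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "horizon": self.horizon,
            "curves": [
                {"index": c.index, "mu": c.mu, "fwhm": c.fwhm,
                 "sigma": c.sigma, "degenerate": c.degenerate}
                for c in self.curves
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "TuningCurveSet":
        curves = tuple(
            TuningCurve(c["index"], c["mu"], c["fwhm"], c["sigma"], c["degenerate"])
            for c in d["curves"]
        )
        return cls(curves, d.get("provenance", "static_uniform"), d.get("horizon"))

    @classmethod
    def from_json(cls, path) -> "TuningCurveSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def speed_response(speed, curve: TuningCurve, cutoff: float = 4.0):
    """Gaussian activation of one curve, clipped to zero beyond ``cutoff`` sigmas."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    if curve.sigma == 0:
        return (speed == curve.mu).astype(float)
    z = (speed - curve.mu) / curve.sigma
    return np.where(np.abs(z) <= cutoff, np.exp(-0.5 * z * z), 0.0)


def derive_tuning(
    dist: SpeedDistribution,
    n_neurons: int = 7,
    placement: str = "literal_eq2",
    sigma_floor: float | None = None,
    provenance: str = "static_uniform",
    horizon: int | None = None,
) -> TuningCurveSet:
    """Allocate N Gaussian curves to a speed distribution.

    ``placement='literal_eq2'`` puts mu_n at the level-n/N quantile (the n-th
    curve peaks where the cumulative density reaches n), which places the last
    peak at the distribution maximum; ``'half_offset'`` uses levels (n-1/2)/N,
    the centered-quantile variant.  Widths follow FWHM_n = 1/d(mu_n) and
    sigma_n = FWHM_n / 2.355.

    A point-mass distribution collapses every curve onto the single observed
    speed; the curves are flagged degenerate rather than raising, because that
    limit is a real behaviour of the dynamic encoder at very short horizons.
    An optional ``sigma_floor`` (degrees/frame) stabilizes this limit.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if placement not in ("literal_eq2", "half_offset"):
        raise ValueError(f"unknown placement {placement!r}")

    if dist.is_point_mass:
        v = float(dist.bin_edges[0])
        sig = float(sigma_floor) if sigma_floor else 0.0
        curves = tuple(
            TuningCurve(n, v, sig * FWHM_OVER_SIGMA, sig, degenerate=True)
            for n in range(1, n_neurons + 1)
        )
        return TuningCurveSet(curves, provenance, horizon)

    n = np.arange(1, n_neurons + 1, dtype=float)
    levels = n / n_neurons if placement == "literal_eq2" else (n - 0.5) / n_neurons
    mu = dist.quantile(levels)
    dens = n_neurons * dist.pdf(mu)  # d(s) = N p(s)
    dens = np.maximum(dens, np.finfo(float).tiny)
    fwhm = 1.0 / dens
    sigma = fwhm / FWHM_OVER_SIGMA
    if sigma_floor is not None:
        sigma = np.maximum(sigma, sigma_floor)
        fwhm = sigma * FWHM_OVER_SIGMA
    curves = tuple(
        TuningCurve(int(i + 1), float(mu[i]), float(fwhm[i]), float(sigma[i]))
        for i in range(n_neurons)
    )
    return TuningCurveSet(curves, provenance, horizon)


def _magnitudes(flow) -> np.ndarray:
    """Flow magnitudes pooled over the full field (sky pixels included as stored)."""
    if hasattr(flow, "speed"):
        return np.asarray(flow.speed(), dtype=float).ravel()
    return np.asarray(flow, dtype=float).ravel()


def build_speed_distribution(flow_fields, bins: int = 128) -> SpeedDistribution:
    """Pool vector magnitudes over all pixels of all fields, equally weighted."""
    fields = list(flow_fields)
    if not fields:
        raise NoFlowDataError("no flow data")
    return SpeedDistribution.from_samples(
        np.concatenate([_magnitudes(f) for f in fields]), bins=bins
    )


class RollingHorizon:
    """FIFO pool of the speed samples from the most recent ``horizon_frames`` frames.

    Every stored vector is weighted equally in the pooled distribution; the
    oldest frame is evicted once the buffer is full.  Before the buffer first
    fills, whatever frames exist are pooled.
    """

    def __init__(self, horizon_frames: int, bins: int = 128):
        if horizon_frames < 1:
            raise ValueError("horizon_frames must be >= 1")
        self.horizon_frames = int(horizon_frames)
        self.bins = int(bins)
        self._buffer: deque = deque(maxlen=self.horizon_frames)

    def __len__(self) -> int:
        return len(self._buffer)

    @property
    def full(self) -> bool:
        return len(self._buffer) == self.horizon_frames

    def update(self, flow) -> SpeedDistribution:
        """Push one frame and return the pooled distribution over the buffer."""
        self._buffer.append(_magnitudes(flow))
        return self.distribution()

    def distribution(self) -> SpeedDistribution:
        if not self._buffer:
            raise NoFlowDataError("no flow data")
        return SpeedDistribution.from_samples(
            np.concatenate(list(self._buffer)), bins=self.bins
        )

    def reset(self) -> None:
        self._buffer.clear()


def update_horizon(h: RollingHorizon, frame) -> SpeedDistribution:
    """Functional alias for :meth:`RollingHorizon.update`."""
    return h.update(frame)


class EfficientSpeedEncoder(TransformerMixin, BaseEstimator):
    """Quantile-allocated Gaussian speed population as a transformer.

    ``fit`` accepts a 1-D array of speed samples (or an ``(n, 1)`` column), a
    :class:`SpeedDistribution`, or a sequence of flow fields, derives the
    equal-mass tuning, and exposes it through ``mu_``, ``sigma_``, ``fwhm_``
    and ``tuning_``.  ``transform`` maps speeds to the ``(n_samples,
    n_neurons)`` matrix of Gaussian activations in [0, 1].

    Parameters
    ----------
    n_neurons : int, default 7
        Population size N (seven unique speed preferences per macrocolumn).
    bins : int, default 128
        Histogram resolution used when fitting from raw samples.
    placement : {'literal_eq2', 'half_offset'}, default 'literal_eq2'
        Quantile levels n/N versus (n-1/2)/N.
    sigma_floor : float or None, default None
        Optional minimum sigma (degrees/frame) guarding the collapsed limit.
    cutoff : float, default 4.0
        Responses are clipped to zero beyond ``cutoff`` sigmas from the peak.
    """

    def __init__(self, n_neurons: int = 7, bins: int = 128,
                 placement: str = "literal_eq2", sigma_floor: float | None = None,
                 cutoff: float = 4.0):
        self.n_neurons = n_neurons
        self.bins = bins
        self.placement = placement
        self.sigma_floor = sigma_floor
        self.cutoff = cutoff

    def fit(self, X, y=None):
        if isinstance(X, SpeedDistribution):
            dist = X
        elif hasattr(X, "__len__") and len(X) and hasattr(X[0], "speed"):
            dist = build_speed_distribution(X, bins=self.bins)
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 2 and X.shape[1] == 1:
                X = X[:, 0]
            dist = SpeedDistribution.from_samples(X, bins=self.bins)
        self.distribution_ = dist
        self.tuning_ = derive_tuning(
            dist, self.n_neurons, self.placement, self.sigma_floor
        )
        self.mu_ = self.tuning_.mu
        self.sigma_ = self.tuning_.sigma
        self.fwhm_ = self.tuning_.fwhm
        self.degenerate_ = self.tuning_.degenerate
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "tuning_"):
            raise RuntimeError("EfficientSpeedEncoder is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        return self.tuning_.response(X, cutoff=self.cutoff)
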