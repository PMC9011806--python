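"""Readers/writers and run plumbing: .flo files, CSV/JSON outputs, config.

Flow fields are exchanged in the Middlebury .flo layout: little-endian
float32 sanity magic 202021.25, int32 width, int32 height, then row-major
interleaved float32 (u, v) pairs.  Flow is stored in pixels/frame; the
degrees-per-pixel conversion factor (fov/grid) is recorded in a JSON
sidecar next to each file so angular units round-trip exactly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .flow import FlowField

FLO_MAGIC = 202021.25


class FloFormatError(ValueError):
    """Malformed .flo file (bad magic, truncated payload...)."""


def write_flo(path, u: np.ndarray, v: np.ndarray) -> None:
    """Write a flow field (pixel units) bit-exactly in .flo layout."""
    u = np.asarray(u, dtype="<f4")
    v = np.asarray(v, dtype="<f4")
    if u.shape != v.shape or u.ndim != 2:
        raise ValueError("u and v must be matching 2-D arrays")
    h, w = u.shape
    data = np.empty((h, w, 2), dtype="<f4")
    data[..., 0] = u
    data[..., 1] = v
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        fh.write(data.tobytes())


def read_flo(path):
    """Read a .flo file; returns (u, v) in pixel units."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 12:
        raise FloFormatError(f"{path}: truncated header at byte {len(raw)}")
    (magic,) = struct.unpack_from("<f", raw, 0)
    if abs(magic - FLO_MAGIC) > 1e-3:
        raise FloFormatError(f"{path}: bad magic {magic!r} at byte 0")
    w, h = struct.unpack_from("<ii", raw, 4)
    if w <= 0 or h <= 0:
        raise FloFormatError(f"{path}: invalid dimensions {w}x{h} at byte 4")
    need = 12 + 8 * w * h
    if len(raw) < need:
        raise FloFormatError(
            f"{path}: truncated payload at byte {len(raw)} (expected {need})")
    data = np.frombuffer(raw, dtype="<f4", offset=12, count=2 * w * h)
    data = data.reshape(h, w, 2)
    return data[..., 0].copy(), data[..., 1].copy()


def write_flow_field(path, flow: FlowField) -> None:
    """Write an angular flow field as .flo (pixels) plus a JSON sidecar."""
    path = Path(path)
    dpp = flow.fov_deg / flow.grid
    write_flo(path, flow.u / dpp, flow.v / dpp)
    sidecar = {
        "degrees_per_pixel": dpp,
        "fov_deg": flow.fov_deg,
        "frame": flow.frame,
        "heading_az": flow.heading_az,
        "heading_el": flow.heading_el,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))


def read_flow_field(path) -> FlowField:
    """Read a .flo file and its sidecar back into angular units."""
    path = Path(path)
    up, vp = read_flo(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    dpp = side["degrees_per_pixel"]
    return FlowField(up * dpp, vp * dpp, np.ones_like(up, bool),
                     side["heading_az"], side["heading_el"],
                     side["fov_deg"], side.get("frame", 0))


def write_truth_csv(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False,
                 columns=["frame", "azimuth_deg", "elevation_deg",
                          "segment_index", "is_transition"])


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configuration and seeding
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All tunables with their defaults; serialized alongside every run."""

    mt_grid: int = 256
    n_directions: int = 24
    n_speeds: int = 7
    pooling_sigma: float = 1.0
    kappa: float = 10.0
    mstd_grid: int = 64
    fov_deg: float = 90.0
    horizon_frames: int = 10
    static_uniform_range: tuple = (0.0, 5.3)
    leak: float = 0.05
    inhibition: float = 1.0
    bins: int = 128
    placement: str = "literal_eq2"
    sigma_floor: float | None = None
    noise_sigma: float = 0.0
    sky_outlier_rate: float = 0.0
    scene_kind: str = "cluttered"
    n_trials: int = 10
    seed: int = 0
    # desk-scale grids used by the experiment harness
    experiment_mt_grid: int = 32
    experiment_mstd_grid: int = 32

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["static_uniform_range"] = list(d["static_uniform_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "static_uniform_range" in d:
            d["static_uniform_range"] = tuple(d["static_uniform_range"])
        return cls(**d)


def stage_seed(master: int, *key) -> int:
    """Counter-based child seed so stages can be re-run in isolation."""
    return int(np.random.SeedSequence([int(master), *map(int, key)])
               .generate_state(1)[0] % (2**31))


def dump_summary_json(path, summaries: dict) -> None:
    """Serialize per-condition summaries (arrays included) deterministically."""
    out = {}
    for label, s in summaries.items():
        fit = s["logistic"]
        out[label] = {
            "converged_error_mean": s["converged_error_mean"],
            "converged_error_ci": list(s["converged_error_ci"]),
            "frame15_error_mean": s["frame15_error_mean"],
            "convergence_frame": s["convergence_frame"],
            "logistic": {"upper": fit.upper, "lower": fit.lower,
                         "rate": fit.rate, "midpoint": fit.midpoint,
                         "n_parameters": 4, "loss": "least_squares"},
            "failed_fits": s["failed_fits"],
            "transition_error_mean": s["transition_error_mean"],
            "late_segment_error_mean": s["late_segment_error_mean"],
            "degenerate_frames": s["degenerate_frames"],
            "held_frames": s["held_frames"],
            "mean_error_per_frame": [round(float(x), 10)
                                     for x in s["mean_error_per_frame"]],
        }
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True))
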