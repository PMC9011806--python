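"""Shared test utilities: synthetic radial flow and brute-force oracles."""

import math

import numpy as np

from dese.encoding import SpeedDistribution, derive_tuning
from dese.flow import FlowField
from dese.mt import MTPopulation


def radial_flow(camera, foe_az, foe_el, scale=1.0):
    """Noiseless radial expansion about an angular FoE position."""
    az, el = camera.pixel_angles()
    u = az - foe_az
    v = el - foe_el
    r = np.hypot(u, v)
    rs = np.where(r > 0, r, 1.0)
    mag = scale * np.clip(r / 45.0, 0.0, 1.0) * 2.0
    return FlowField(u / rs * mag, v / rs * mag,
                     np.ones_like(u, bool), foe_az, foe_el, camera.fov_deg)


def oracle_template_argmax(flow, bank):
    """Brute-force radial-template match computed from raw flow directions.

    Independent of the MT/MSTd code path: rectified cosine alignment between
    the unit flow vectors and each template's radial direction, evaluated for
    every template.
    """
    u = flow.u.ravel()
    v = flow.v.ravel()
    m = np.hypot(u, v)
    sel = m > 0
    du = u[sel] / m[sel]
    dv = v[sel] / m[sel]
    drive = np.empty(bank.n_templates)
    for t in range(bank.n_templates):
        align = bank._cos[t, sel] * du + bank._sin[t, sel] * dv
        drive[t] = np.maximum(align, 0.0).sum()
    return divmod(int(np.argmax(drive)), bank.grid)


def dynamic_mt_response(flow, grid, bins=64):
    """MT response under a tuning freshly fit to the field's own speeds."""
    tuning = derive_tuning(
        SpeedDistribution.from_samples(flow.speed().ravel(), bins), 7)
    return MTPopulation(grid=grid, tuning=tuning).transform(flow)


def finite_difference_oracle(scene, pose_t, pose_t1, camera):
    """Scalar-loop reprojection oracle for flow rendering."""
    G = camera.grid
    t = math.tan(math.radians(camera.fov_deg / 2))
    u = np.zeros((G, G))
    v = np.zeros((G, G))
    ok = np.zeros((G, G), bool)
    R0 = pose_t.rotation.as_matrix()
    R1 = pose_t1.rotation.as_matrix()
    for r in range(G):
        for c in range(G):
            x = -t + 2 * t * (c + 0.5) / G
            y = t - 2 * t * (r + 0.5) / G
            d = np.array([x, y, 1.0])
            d /= np.linalg.norm(d)
            dw = R0 @ d
            depth = float(scene.ray_depth(pose_t.position, dw[None, :])[0])
            if not np.isfinite(depth) or depth <= 0:
                continue
            P = pose_t.position + depth * dw
            q = R1.T @ (P - pose_t1.position)
            if q[2] <= 0:
                continue
            u[r, c] = math.degrees(math.atan(q[0] / q[2])) - math.degrees(math.atan(x))
            v[r, c] = math.degrees(math.atan(q[1] / q[2])) - math.degrees(math.atan(y))
            ok[r, c] = True
    return u, v, ok


def random_distribution(rng, n_samples=4000, bins=None):
    """A random mixed lognormal speed distribution (never degenerate)."""
    k = rng.integers(1, 4)
    parts = [rng.lognormal(rng.normal(0, 1), rng.uniform(0.2, 1.0),
                           size=n_samples // k) for _ in range(k)]
    samples = np.concatenate(parts)
    return SpeedDistribution.from_samples(
        samples, bins=int(bins or rng.integers(16, 129)))
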