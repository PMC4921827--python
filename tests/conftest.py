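"""Shared fixtures and independent oracles.

SNR follows the single-particle EM convention: signal variance over noise
variance, so at SNR 1 the added noise sd equals the sd of the noiseless
image.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cscmorph.synthgen import (GroundTruthRecord, LobeTruth, SimulationConfig,
                               _render_particle)

BOX_PX = 41
PIXEL_SIZE = 0.25


def render_lobe_box(shape_class: str, rng: np.random.Generator | None = None,
                    snr: float | None = None, area: float = 39.9,
                    orientation: float | None = None, box: int = BOX_PX,
                    pixel_size: float = PIXEL_SIZE) -> np.ndarray:
    """One bright-polarity lobe image, optionally noisy at a given SNR."""
    cfg = SimulationConfig(n_particles=1, seed=0, noise_sd=0.0, halo_strength=0.0)
    center = (box * pixel_size / 2, box * pixel_size / 2)
    if shape_class == "triangular":
        if orientation is None:
            orientation = float(rng.uniform(0, 360)) if rng is not None else 0.0
    else:
        orientation = float("nan")
    lobe = LobeTruth(center, area, shape_class, orientation)
    rec = GroundTruthRecord(0, center, (lobe,))
    img = np.full((box, box), cfg.background)
    _render_particle(img, cfg, rec)
    if snr is not None:
        img = img + rng.normal(0.0, img.std() / math.sqrt(snr), img.shape)
    return (img.max() + img.min()) - img


def brute_force_enclosing_circle(points) -> tuple[tuple[float, float], float]:
    """O(n^3) minimum enclosing circle: try every 2- and 3-point support set."""
    pts = [tuple(map(float, p)) for p in np.atleast_2d(points)]
    best = None

    def check(cx, cy, r):
        nonlocal best
        if all(math.hypot(x - cx, y - cy) <= r + 1e-9 for x, y in pts):
            if best is None or r < best[1]:
                best = ((cx, cy), r)

    n = len(pts)
    if n == 1:
        return pts[0], 0.0
    for i in range(n):
        for j in range(i + 1, n):
            cx = (pts[i][0] + pts[j][0]) / 2
            cy = (pts[i][1] + pts[j][1]) / 2
            check(cx, cy, math.hypot(pts[i][0] - cx, pts[i][1] - cy))
            for k in range(j + 1, n):
                (ax, ay), (bx, by), (qx, qy) = pts[i], pts[j], pts[k]
                d = 2.0 * (ax * (by - qy) + bx * (qy - ay) + qx * (ay - by))
                if abs(d) < 1e-14:
                    continue
                ux = ((ax * ax + ay * ay) * (by - qy) + (bx * bx + by * by) * (qy - ay)
                      + (qx * qx + qy * qy) * (ay - by)) / d
                uy = ((ax * ax + ay * ay) * (qx - bx) + (bx * bx + by * by) * (ax - qx)
                      + (qx * qx + qy * qy) * (bx - ax)) / d
                check(ux, uy, math.hypot(ax - ux, ay - uy))
    return best


def monte_carlo_union_area(disks, n_samples: int, rng: np.random.Generator) -> float:
    """Uniform rejection sampling over the bounding box of the disk set."""
    x0, y0, x1, y1 = disks.bounds
    pts = rng.uniform([x0, y0], [x1, y1], size=(n_samples, 2))
    inside = np.zeros(n_samples, dtype=bool)
    for cx, cy, r in zip(disks.x, disks.y, disks.r):
        inside |= (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 <= r * r
    return float(inside.mean()) * (x1 - x0) * (y1 - y0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """300 noiseless six-lobed particles with their measurements (shared)."""
    from cscmorph import metrology, synthgen

    cfg = SimulationConfig(n_particles=300, seed=7, noise_sd=0.0,
                           halo_strength=0.0, five_lobe_fraction=0.0)
    micrograph, records = synthgen.simulate_micrograph(cfg)
    polys = {r.particle_id: [synthgen.lobe_outline(l) for l in r.lobes]
             for r in records}
    measurements, excluded = metrology.measure_cohort(polys)
    return cfg, micrograph, records, measurements, excluded
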