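"""Lobe triangularity scoring.

Visual assessments of rosette CSC lobes range from clearly triangular
(one vertex pointing to the particle centre) to round, with the triangular
fraction depending on how strictly a triangle is defined.  This module
formalizes that judgement:

    T = max_theta IoU(mask, equal-area equilateral triangle(theta))
        - IoU(mask, equal-area disc)

Both reference shapes are centred on the mask centroid; the rotation
search runs over [0, 120) degrees in 1-degree steps (triangle symmetry).
T > 0 means the lobe is better explained by a triangle than by a disc.
The population-level statement is a fraction-vs-threshold curve, not a
single number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as _cc_label

__all__ = [
    "LobeShapeScore",
    "lobe_mask",
    "triangularity",
    "triangular_fraction",
]


@dataclass(frozen=True)
class LobeShapeScore:
    """Triangularity of one lobe mask."""

    triangularity: float         # T = IoU_triangle - IoU_disc, in [-1, 1]
    iou_triangle: float
    iou_disc: float
    rotation_deg: float          # best-fit triangle rotation in [0, 120)
    vertex_to_center_deg: float  # signed angle of nearest vertex to the centre
    #                              direction, in [-60, 60]; NaN if unknown
    mask_area_nm2: float
    low_confidence: bool         # mask touches the box border


def lobe_mask(lobe_image: np.ndarray) -> np.ndarray:
    """Binary lobe mask: Otsu threshold, largest component, holes filled.

    Expects bright-lobe polarity (inverted contrast).
    """
    img = np.asarray(lobe_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("lobe image must be 2-D")
    if img.max() - img.min() < 1e-12:
        raise ValueError("lobe image has no contrast; empty foreground")
    mask = img >= threshold_otsu(img)
    if not mask.any():
        raise ValueError("empty foreground after thresholding")
    labels = _cc_label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    return ndimage.binary_fill_holes(mask)


def _pixel_grid(shape: tuple[int, int], pixel_size: float,
                centroid_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xs + 0.5) * pixel_size - centroid_nm[0],
            (ys + 0.5) * pixel_size - centroid_nm[1])


def _triangle_mask(dx: np.ndarray, dy: np.ndarray, area: float,
                   theta_deg: float) -> np.ndarray:
    """Equilateral triangle of the given area, one vertex at theta."""
    circum = math.sqrt(4.0 * area / math.sqrt(3.0)) / math.sqrt(3.0)
    ang = np.deg2rad(theta_deg) + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    vx, vy = circum * np.cos(ang), circum * np.sin(ang)
    inside = np.ones(dx.shape, dtype=bool)
    for i in range(3):
        j = (i + 1) % 3
        ex, ey = vx[j] - vx[i], vy[j] - vy[i]
        cross = ex * (dy - vy[i]) - ey * (dx - vx[i])
        # vertices are ordered CCW in (x, y-down): keep the consistent side
        inside &= cross >= 0
    return inside


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 0.0


def triangularity(mask: np.ndarray, pixel_size: float,
                  center_direction_deg: float | None = None,
                  angle_step: float = 1.0) -> LobeShapeScore:
    """Score a lobe mask against equal-area triangle and disc references.

    ``center_direction_deg``, if given, is the image-frame direction from
    the lobe centroid toward the particle centre; the score then reports
    the signed offset of the nearest triangle vertex from that direction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    border = (mask[0].any() or mask[-1].any()
              or mask[:, 0].any() or mask[:, -1].any())
    area = float(mask.sum()) * pixel_size ** 2
    ys, xs = np.nonzero(mask)
    centroid = np.array([(xs.mean() + 0.5) * pixel_size,
                         (ys.mean() + 0.5) * pixel_size])
    dx, dy = _pixel_grid(mask.shape, pixel_size, centroid)

    disc = (dx ** 2 + dy ** 2) <= area / math.pi
    iou_disc = _iou(mask, disc)

    thetas = np.arange(0.0, 120.0, angle_step)
    best_iou, best_theta = -1.0, 0.0
    for theta in thetas:
        v = _iou(mask, _triangle_mask(dx, dy, area, theta))
        if v > best_iou:
            best_iou, best_theta = v, float(theta)

    if center_direction_deg is None or not np.isfinite(center_direction_deg):
        vertex_offset = float("nan")
    else:
        # candidate vertex directions are best_theta + k*120
        cands = (best_theta + np.array([0.0, 120.0, 240.0])) % 360.0
        diffs = (cands - center_direction_deg + 180.0) % 360.0 - 180.0
        vertex_offset = float(diffs[np.argmin(np.abs(diffs))])
    return LobeShapeScore(best_iou - iou_disc, best_iou, iou_disc,
                          best_theta, vertex_offset, area, bool(border))


def triangular_fraction(scores, thresholds=None) -> pd.DataFrame:
    """Fraction of lobes with T > threshold, over a threshold sweep.

    Returns a DataFrame with columns ``threshold`` and ``fraction``; the
    curve is non-increasing by construction.  No single "true" fraction is
    claimed: strictness is the free parameter.
    """
    t_vals = np.asarray([s.triangularity if isinstance(s, LobeShapeScore) else float(s)
                         for s in scores])
    if t_vals.size == 0:
        raise ValueError("need at least one score")
    if thresholds is None:
        thresholds = np.round(np.arange(-0.2, 0.301, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    frac = [(t_vals > thr).mean() for thr in thresholds]
    return pd.DataFrame({"threshold": thresholds, "fraction": frac})
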