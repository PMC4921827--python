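"""Particle metrology: the measurement procedure applied to rosette CSCs.

Diameter is estimated two ways, mirroring the hand-measurement protocol:

* *circular geometry*: the smallest circle containing all six lobes gives
  a perimeter ``P_circ``; the diameter is ``d_circ = P_circ / pi``.
* *hexagonal geometry*: the irregular hexagon through the outer centre
  edge of each lobe gives ``P_hex``; the diameter uses the across-flats
  relation of a regular hexagon, ``d_hex = (sqrt(3)/6) * P_hex``.  (The
  across-corners convention would give d = P/3 and is clearly incompatible
  with the published perimeter/diameter pairs.)

Lobe areas are shoelace polygon areas; opposite-lobe spacings are centroid
distances of lobe pairs (i, i+3) after ordering by polar angle.
Summary tables report per-group mean +/- sample SD (n-1) and an overall
row that is the *unweighted* mean of the group means, the convention that
reproduces the published overall means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "Circle",
    "RosetteMeasurement",
    "SummaryTable",
    "ParticleExcluded",
    "SelfIntersectionError",
    "smallest_enclosing_circle",
    "circular_estimate",
    "hexagonal_estimate",
    "lobe_area",
    "opposite_lobe_spacings",
    "measure_particle",
    "measure_cohort",
    "summarize",
]

HEX_ACROSS_FLATS = math.sqrt(3) / 6.0  # d_hex = this * P_hex


class ParticleExcluded(ValueError):
    """Particle does not meet the 6-lobe measurement precondition."""


class SelfIntersectionError(ValueError):
    """Polygon is not simple; message names the offending segment pair."""


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float

    def contains(self, p, tol: float = 1e-9) -> bool:
        return math.hypot(p[0] - self.center[0], p[1] - self.center[1]) <= self.radius + tol


def _circle_from_2(a, b) -> Circle:
    cx, cy = (a[0] + b[0]) / 2.0, (a[1] + b[1]) / 2.0
    return Circle((cx, cy), math.hypot(a[0] - cx, a[1] - cy))


def _circle_from_3(a, b, c) -> Circle | None:
    ax, ay = a; bx, by = b; cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-14:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    return Circle((ux, uy), math.hypot(ax - ux, ay - uy))


def smallest_enclosing_circle(points) -> Circle:
    """Minimum enclosing circle (Welzl's move-to-front algorithm).

    Deterministic: the input is shuffled with a fixed-seed generator, which
    affects only the running time, never the (unique) result.
    """
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.size == 0:
        raise ValueError("smallest_enclosing_circle requires at least one point")
    pts = [tuple(map(float, p)) for p in arr]
    rng = np.random.default_rng(0)
    pts = [pts[i] for i in rng.permutation(len(pts))]

    c: Circle | None = None
    for i, p in enumerate(pts):
        if c is not None and c.contains(p):
            continue
        c = Circle(p, 0.0)
        for j in range(i):
            q = pts[j]
            if c.contains(q):
                continue
            c = _circle_from_2(p, q)
            for k in range(j):
                r = pts[k]
                if c.contains(r):
                    continue
                c3 = _circle_from_3(p, q, r)
                c = c3 if c3 is not None else _circle_from_2(
                    *max(((p, q), (p, r), (q, r)),
                         key=lambda ab: math.hypot(ab[0][0] - ab[1][0],
                                                   ab[0][1] - ab[1][1])))
    return c


def circular_estimate(lobe_outer_points, n_lobes: int = 6) -> tuple[float, float]:
    """(P_circ, d_circ) from the smallest circle over all lobe edge points.

    ``n_lobes`` declares how many lobes the points came from; anything
    other than six raises :class:`ParticleExcluded` (five-lobed or
    indistinct particles are counted but not measured).
    """
    if n_lobes != 6:
        raise ParticleExcluded(f"particle has {n_lobes} identified lobes, need 6")
    c = smallest_enclosing_circle(lobe_outer_points)
    p = 2.0 * math.pi * c.radius
    return p, p / math.pi


def hexagonal_estimate(lobe_edge_midpoints) -> tuple[float, float]:
    """(P_hex, d_hex) from the irregular hexagon through six outer-edge points.

    Points are re-ordered by polar angle about their centroid so crossing
    input orders cannot produce a self-intersecting hexagon.
    """
    pts = np.asarray(lobe_edge_midpoints, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError("hexagonal_estimate requires exactly 6 points")
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    pts = pts[np.argsort(ang)]
    sides = np.hypot(*(pts - np.roll(pts, -1, axis=0)).T)
    if np.any(sides < 1e-12) or Polygon(pts).area < 1e-12:
        raise ValueError("degenerate (collinear or coincident) hexagon points")
    p_hex = float(sides.sum())
    return p_hex, HEX_ACROSS_FLATS * p_hex


def _find_crossing(pts: np.ndarray) -> tuple[int, int] | None:
    n = len(pts)
    segs = [(pts[i], pts[(i + 1) % n]) for i in range(n)]

    def cross2(u, v) -> float:
        return u[0] * v[1] - u[1] * v[0]

    def crosses(s1, s2) -> bool:
        (p1, p2), (p3, p4) = s1, s2
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through wrap-around
            if crosses(segs[i], segs[j]):
                return i, j
    return None


def lobe_area(polygon) -> float:
    """Absolute shoelace area of a simple closed polygon (nm^2).

    Orientation-independent; self-intersecting input raises
    :class:`SelfIntersectionError` naming the crossing segment pair.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    poly = Polygon(pts)
    if not poly.is_simple:
        pair = _find_crossing(pts)
        raise SelfIntersectionError(
            f"polygon is self-intersecting: segments {pair[0]} and {pair[1]} cross")
    return abs(poly.area)


def opposite_lobe_spacings(lobe_centroids) -> tuple[np.ndarray, float]:
    """Distances between opposite lobe centroids (pairs i, i+3) and their mean.

    Centroids must be six points; they are ordered by polar angle about
    their mean before pairing.
    """
    pts = np.asarray(lobe_centroids, dtype=float)
    if pts.shape != (6, 2):
        raise ValueError("opposite_lobe_spacings requires exactly 6 centroids")
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - centroid[1], pts[:, 0] - centroid[0])
    pts = pts[np.argsort(ang)]
    d = np.hypot(*(pts[:3] - pts[3:]).T)
    return d, float(d.mean())


@dataclass(frozen=True)
class RosetteMeasurement:
    """Per-particle measurement record (all lengths nm, areas nm^2)."""

    particle_id: int
    lobe_centroids: np.ndarray    # (6, 2), ordered by polar angle
    lobe_polygons: tuple          # 6 vertex arrays, same order
    P_circ: float
    d_circ: float
    P_hex: float
    d_hex: float
    lobe_areas: np.ndarray        # (6,)
    opposite_spacings: np.ndarray  # (3,)

    @property
    def mean_lobe_area(self) -> float:
        return float(self.lobe_areas.mean())

    @property
    def mean_opposite_spacing(self) -> float:
        return float(self.opposite_spacings.mean())


def measure_particle(lobe_polygons, particle_id: int = 0) -> RosetteMeasurement:
    """Measure one particle from its six traced lobe outlines.

    The circular estimate uses *all* polygon vertices; the hexagonal
    estimate uses, per lobe, the boundary vertex farthest from the particle
    centre (the outer centre edge of the lobe).
    """
    polys = [np.asarray(p, dtype=float) for p in lobe_polygons]
    if len(polys) != 6:
        raise ParticleExcluded(f"particle {particle_id} has {len(polys)} lobes, need 6")
    sh = [Polygon(p) for p in polys]
    for i, s in enumerate(sh):
        if not s.is_simple:
            pair = _find_crossing(polys[i])
            raise SelfIntersectionError(
                f"lobe {i}: segments {pair[0]} and {pair[1]} cross")
    centroids = np.array([[s.centroid.x, s.centroid.y] for s in sh])
    center = centroids.mean(axis=0)
    order = np.argsort(np.arctan2(centroids[:, 1] - center[1],
                                  centroids[:, 0] - center[0]))
    polys = [polys[i] for i in order]
    centroids = centroids[order]

    all_pts = np.vstack(polys)
    P_circ, d_circ = circular_estimate(all_pts)
    outer = []
    for p in polys:
        d = np.hypot(p[:, 0] - center[0], p[:, 1] - center[1])
        outer.append(p[int(np.argmax(d))])
    P_hex, d_hex = hexagonal_estimate(np.asarray(outer))
    areas = np.array([lobe_area(p) for p in polys])
    spacings, _ = opposite_lobe_spacings(centroids)
    return RosetteMeasurement(particle_id, centroids, tuple(polys),
                              P_circ, d_circ, P_hex, d_hex, areas, spacings)


def measure_cohort(polygons_by_particle: dict[int, list]
                   ) -> tuple[list[RosetteMeasurement], list[int]]:
    """Measure every 6-lobed particle; return (measurements, excluded ids).

    Particles without exactly six lobes are excluded and logged, mirroring
    the published protocol in which 324 of 497 particles were measurable.
    """
    out, excluded = [], []
    for pid, polys in polygons_by_particle.items():
        try:
            out.append(measure_particle(polys, particle_id=pid))
        except ParticleExcluded as e:
            logger.info("excluding particle %s: %s", pid, e)
            excluded.append(pid)
    return out, excluded


@dataclass(frozen=True)
class SummaryTable:
    """Per-group statistics plus the unweighted overall row."""

    per_group: pd.DataFrame   # index: group; columns: <col>_mean, <col>_sd, <col>_n
    overall: pd.Series        # unweighted mean of group means per column

    def round(self, decimals: int = 1) -> "SummaryTable":
        return SummaryTable(self.per_group.round(decimals), self.overall.round(decimals))


def summarize(values_by_group: dict[str, dict[str, list]] | pd.DataFrame,
              group_col: str = "group") -> SummaryTable:
    """Summarize measured quantities by group.

    Accepts either a tidy DataFrame with a ``group_col`` plus numeric
    columns, or a mapping ``{group: {column: values}}``.  Per group:
    mean and sample SD (n-1 denominator; absent for n=1).  The overall row
    is the unweighted mean of the group means.  Empty groups are omitted
    with a warning.
    """
    if isinstance(values_by_group, pd.DataFrame):
        df = values_by_group
        groups = {g: {c: sub[c].dropna().tolist()
                      for c in df.columns if c != group_col}
                  for g, sub in df.groupby(group_col, sort=False)}
    else:
        groups = values_by_group
    if not groups:
        raise ValueError("summarize requires at least one group")
    rows = {}
    for g, cols in groups.items():
        if all(len(v) == 0 for v in cols.values()):
            logger.warning("group %r is empty; omitted from summary", g)
            continue
        row = {}
        for c, vals in cols.items():
            arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
            row[f"{c}_mean"] = arr.mean() if arr.size else np.nan
            row[f"{c}_sd"] = arr.std(ddof=1) if arr.size > 1 else np.nan
            row[f"{c}_n"] = arr.size
        rows[g] = row
    per_group = pd.DataFrame.from_dict(rows, orient="index")
    mean_cols = [c for c in per_group.columns if c.endswith("_mean")]
    overall = per_group[mean_cols].mean(axis=0, skipna=True)
    return SummaryTable(per_group, overall)


def measurements_to_tsv(measurements: list[RosetteMeasurement], path) -> None:
    """One row per particle; lobe polygons as WKT in a companion column."""
    rows = []
    for m in measurements:
        rows.append({
            "particle_id": m.particle_id,
            "P_circ_nm": m.P_circ, "d_circ_nm": m.d_circ,
            "P_hex_nm": m.P_hex, "d_hex_nm": m.d_hex,
            "mean_lobe_area_nm2": m.mean_lobe_area,
            "mean_opposite_spacing_nm": m.mean_opposite_spacing,
            **{f"lobe_area_{i}_nm2": a for i, a in enumerate(m.lobe_areas)},
            **{f"opposite_spacing_{i}_nm": s for i, s in enumerate(m.opposite_spacings)},
            "lobes_wkt": shapely.geometry.MultiPolygon(
                [Polygon(p) for p in m.lobe_polygons]).wkt,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
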