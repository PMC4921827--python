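"""Seeded synthetic micrographs of rosette-type particles, with ground truth.

The generator emulates the appearance of rosette cellulose synthesis
complexes (CSCs) in freeze-fracture TEM replicas: dark multi-lobed
particles on a lighter membrane background, six lobes equally spaced on a
ring (opposite-lobe centre spacing = 2 x ring radius, ~17 nm), lobe shapes
ranging from rounded equilateral triangles (one vertex pointing to the
particle centre) to discs, a minority of five-lobed particles, an optional
bright decoration halo around each lobe, and additive Gaussian noise.

It also builds toy helix-bundle atomic models (vertical stacks of
pseudo-atoms) so the membrane-footprint stage is testable without any
deposited coordinates.

Everything is driven by one seeded generator with per-particle
sub-streams, so a fixed (seed, config) pair yields a bit-identical
micrograph and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Micrograph

__all__ = [
    "SimulationConfig",
    "LobeTruth",
    "GroundTruthRecord",
    "ToyAtomicModel",
    "SizingError",
    "PackingError",
    "simulate_micrograph",
    "lobe_outline",
    "make_toy_bundle",
    "ground_truth_to_tsv",
    "ground_truth_from_tsv",
]

#: corner-rounding radius of triangular lobes, as a fraction of the side
TRIANGLE_ROUNDING_FRACTION = 0.10

#: area coefficient of the rounded equilateral triangle: area = coeff * side^2
_ROUNDED_TRI_COEFF = (math.sqrt(3) / 4
                      - (3 * math.sqrt(3) - math.pi) * TRIANGLE_ROUNDING_FRACTION ** 2)


class SizingError(ValueError):
    """Raised when particles cannot fit the requested box size."""


class PackingError(ValueError):
    """Raised when a toy-bundle layout places helices on top of each other."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic micrograph.

    Defaults reproduce the imaging geometry reported for rosette CSCs:
    opposite-lobe spacing 17.0 nm (ring radius 8.5 nm), lobe areas
    39.9 +/- 6.5 nm^2, ~9% five-lobed/indistinct particles, and a 31.6 nm
    particle box.
    """

    n_particles: int = 50
    pixel_size: float = 0.25          # nm / pixel
    ring_radius: float = 8.5          # nm; half the opposite-lobe spacing
    lobe_area_mean: float = 39.9      # nm^2
    lobe_area_sd: float = 6.5         # nm^2
    lobe_shape_mix: float = 0.5       # fraction of lobes drawn triangular
    five_lobe_fraction: float = 0.09  # fraction of particles with 5 lobes
    noise_sd: float = 0.15            # additive Gaussian noise, intensity units
    halo_strength: float = 0.08       # decoration-halo brightening
    seed: int = 0
    centroid_jitter_sd: float = 0.35  # nm; isotropic lobe-centroid jitter
    box_size: float = 31.6            # nm; particle box the layout must honour
    background: float = 0.55          # membrane background intensity
    lobe_depth: float = 0.35          # darkening of lobes below background
    halo_width: float = 1.0           # nm; decoration annulus width

    def validate(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        for name in ("pixel_size", "ring_radius", "lobe_area_mean", "box_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lobe_shape_mix", "five_lobe_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.lobe_area_sd < 0 or self.noise_sd < 0 or self.halo_strength < 0:
            raise ValueError("lobe_area_sd, noise_sd, halo_strength must be >= 0")
        # largest plausible lobe: mean + 3 sd (the area draw is truncated there)
        area_hi = self.lobe_area_mean + 3 * self.lobe_area_sd
        reach = self.ring_radius + _lobe_outer_radius(area_hi) + self.halo_width
        if 2 * reach > self.box_size:
            raise SizingError(
                f"particles of radial extent {reach:.2f} nm do not fit a "
                f"{self.box_size:.1f} nm box; increase box_size or shrink the particle"
            )


@dataclass(frozen=True)
class LobeTruth:
    """Ground truth for one rendered lobe."""

    centroid: tuple[float, float]   # nm
    area: float                     # nm^2, true analytic area of the drawn shape
    shape_class: str                # "triangular" | "round"
    orientation_deg: float          # direction (deg) of the inward vertex; NaN for round


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth for one rendered particle."""

    particle_id: int
    center: tuple[float, float]     # nm
    lobes: tuple[LobeTruth, ...]

    @property
    def n_lobes(self) -> int:
        return len(self.lobes)


# ----------------------------------------------------------------- geometry

def _tri_side_for_area(area: float) -> float:
    """Side of the rounded equilateral triangle with the given true area."""
    return math.sqrt(area / _ROUNDED_TRI_COEFF)


def _tri_params(area: float) -> tuple[float, float, float]:
    """Return (side, rounding radius, inner-triangle side) for a lobe area.

    The rounded triangle is the Minkowski sum of an inner equilateral
    triangle (side ``s_in = s - 2*sqrt(3)*rho``) with a disc of radius
    ``rho``; its area is ``A(s_in) + 3*s_in*rho + pi*rho^2``.
    """
    s = _tri_side_for_area(area)
    rho = TRIANGLE_ROUNDING_FRACTION * s
    s_in = s - 2 * math.sqrt(3) * rho
    return s, rho, s_in


def _lobe_outer_radius(area: float) -> float:
    """Max centroid-to-boundary distance over both lobe shapes of this area."""
    s, rho, s_in = _tri_params(area)
    tri = s_in / math.sqrt(3) + rho       # inner circumradius + rounding
    disc = math.sqrt(area / math.pi)
    return max(tri, disc)


def _inner_triangle_vertices(centroid: np.ndarray, s_in: float,
                             orientation_deg: float) -> np.ndarray:
    """Vertices of the inner equilateral triangle, one vertex at
    ``orientation_deg`` (measured in the image frame, y down)."""
    r = s_in / math.sqrt(3)
    ang = np.deg2rad(orientation_deg) + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    return centroid + r * np.stack([np.cos(ang), np.sin(ang)], axis=1)


def _dist_to_triangle(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Unsigned distance from points to a triangle (0 inside)."""
    p = np.stack([px.ravel(), py.ravel()], axis=1)
    inside = np.ones(p.shape[0], dtype=bool)
    dmin = np.full(p.shape[0], np.inf)
    # consistent orientation for the half-plane test
    v = verts
    cross0 = ((v[1, 0] - v[0, 0]) * (v[2, 1] - v[0, 1])
              - (v[1, 1] - v[0, 1]) * (v[2, 0] - v[0, 0]))
    sgn = 1.0 if cross0 >= 0 else -1.0
    for i in range(3):
        a, b = v[i], v[(i + 1) % 3]
        e = b - a
        w = p - a
        cross = e[0] * w[:, 1] - e[1] * w[:, 0]
        inside &= (sgn * cross) >= 0
        t = np.clip((w @ e) / (e @ e), 0.0, 1.0)
        proj = a + t[:, None] * e
        dmin = np.minimum(dmin, np.hypot(*(p - proj).T))
    d = np.where(inside, 0.0, dmin)
    return d.reshape(px.shape)


def _lobe_signed_distance(px: np.ndarray, py: np.ndarray, lobe: LobeTruth) -> np.ndarray:
    """Signed distance to the lobe boundary (negative inside)."""
    c = np.asarray(lobe.centroid)
    if lobe.shape_class == "round":
        return np.hypot(px - c[0], py - c[1]) - math.sqrt(lobe.area / math.pi)
    _, rho, s_in = _tri_params(lobe.area)
    verts = _inner_triangle_vertices(c, s_in, lobe.orientation_deg)
    d_in = _dist_to_triangle(px, py, verts)
    out = d_in - rho
    # inside the rounded shape: d_in <= rho; report a small negative depth
    return np.where(d_in <= rho, d_in - rho - 1e-12, out)


def lobe_outline(lobe: LobeTruth, n_vertices: int = 96) -> np.ndarray:
    """Analytic boundary polygon of a ground-truth lobe, in nm.

    For round lobes this is a regular ``n_vertices``-gon on the circle; for
    triangular lobes it is the exact offset contour (three straight edges
    plus corner arcs sampled at roughly equal angular steps).
    """
    c = np.asarray(lobe.centroid, dtype=float)
    if lobe.shape_class == "round":
        r = math.sqrt(lobe.area / math.pi)
        # use the equal-area polygon radius so the polygon area matches truth
        r_eq = r / math.sqrt(math.sin(2 * math.pi / n_vertices) * n_vertices / (2 * math.pi))
        t = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
        return c + r_eq * np.stack([np.cos(t), np.sin(t)], axis=1)
    _, rho, s_in = _tri_params(lobe.area)
    verts = _inner_triangle_vertices(c, s_in, lobe.orientation_deg)
    centroid = verts.mean(axis=0)
    pts: list[np.ndarray] = []
    n_arc = max(4, n_vertices // 6)
    for i in range(3):
        a, b = verts[i], verts[(i + 1) % 3]
        e = b - a
        n_hat = np.array([e[1], -e[0]]) / np.hypot(*e)
        if np.dot(n_hat, (a + b) / 2 - centroid) < 0:
            n_hat = -n_hat
        pts.append(a + rho * n_hat)
        pts.append(b + rho * n_hat)
        # corner arc around vertex b, from this edge normal to the next
        a2, b2 = verts[(i + 1) % 3], verts[(i + 2) % 3]
        e2 = b2 - a2
        n2 = np.array([e2[1], -e2[0]]) / np.hypot(*e2)
        if np.dot(n2, (a2 + b2) / 2 - centroid) < 0:
            n2 = -n2
        a0 = math.atan2(n_hat[1], n_hat[0])
        a1 = math.atan2(n2[1], n2[0])
        sweep = (a1 - a0) % (2 * math.pi)
        for t in np.linspace(0.0, sweep, n_arc + 2)[1:-1]:
            ang = a0 + t
            pts.append(b + rho * np.array([math.cos(ang), math.sin(ang)]))
    return np.asarray(pts)


# ------------------------------------------------------------- simulation

def _layout_grid(n: int, cell: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Particle centres on a square grid, one particle per cell."""
    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    centers = np.empty((n, 2))
    for i in range(n):
        r, c = divmod(i, ncols)
        centers[i] = ((c + 0.5) * cell, (r + 0.5) * cell)
    return centers, (nrows, ncols)


def _draw_particle(rng: np.random.Generator, cfg: SimulationConfig,
                   pid: int, center: np.ndarray) -> GroundTruthRecord:
    lo = max(1e-6, cfg.lobe_area_mean - 3 * cfg.lobe_area_sd)
    hi = cfg.lobe_area_mean + 3 * cfg.lobe_area_sd

    def draw_area() -> float:
        if cfg.lobe_area_sd == 0:
            return cfg.lobe_area_mean
        while True:
            a = rng.normal(cfg.lobe_area_mean, cfg.lobe_area_sd)
            if lo <= a <= hi:
                return a

    five = rng.random() < cfg.five_lobe_fraction
    drop = int(rng.integers(6)) if five else -1
    global_rot = rng.uniform(0.0, 360.0)
    lobes: list[LobeTruth] = []
    for k in range(6):
        if k == drop:
            continue
        phi = math.radians(global_rot + 60.0 * k)
        centroid = center + cfg.ring_radius * np.array([math.cos(phi), math.sin(phi)])
        if cfg.centroid_jitter_sd > 0:
            centroid = centroid + rng.normal(0.0, cfg.centroid_jitter_sd, size=2)
        area = draw_area()
        triangular = rng.random() < cfg.lobe_shape_mix
        if triangular:
            # inward vertex: direction from the lobe centroid to the particle centre
            d = center - centroid
            orientation = math.degrees(math.atan2(d[1], d[0]))
            lobes.append(LobeTruth(tuple(centroid), area, "triangular", orientation))
        else:
            lobes.append(LobeTruth(tuple(centroid), area, "round", float("nan")))
    return GroundTruthRecord(pid, tuple(center), tuple(lobes))


_SUPERSAMPLE = 3


def _render_particle(template: np.ndarray, cfg: SimulationConfig,
                     rec: GroundTruthRecord) -> None:
    """Rasterize one particle into the template (in place).

    Pixel membership uses >=50% sub-pixel coverage on a 3x3 grid, so the
    rendered pixel count is an unbiased estimate of the true area.
    """
    px = cfg.pixel_size
    rows, cols = template.shape
    for lobe in rec.lobes:
        reach = _lobe_outer_radius(lobe.area) + cfg.halo_width + 2 * px
        c = np.asarray(lobe.centroid)
        c0 = max(0, int((c[0] - reach) / px))
        c1 = min(cols, int(math.ceil((c[0] + reach) / px)))
        r0 = max(0, int((c[1] - reach) / px))
        r1 = min(rows, int(math.ceil((c[1] + reach) / px)))
        if c1 <= c0 or r1 <= r0:
            continue
        sub = _SUPERSAMPLE
        xs = (c0 + (np.arange((c1 - c0) * sub) + 0.5) / sub) * px
        ys = (r0 + (np.arange((r1 - r0) * sub) + 0.5) / sub) * px
        gx, gy = np.meshgrid(xs, ys)
        sd = _lobe_signed_distance(gx, gy, lobe)
        cover = (sd <= 0).reshape(r1 - r0, sub, c1 - c0, sub).mean(axis=(1, 3))
        lobe_mask = cover >= 0.5
        template[r0:r1, c0:c1][lobe_mask] -= cfg.lobe_depth
        if cfg.halo_strength > 0:
            halo = ((sd > 0) & (sd <= cfg.halo_width)
                    ).reshape(r1 - r0, sub, c1 - c0, sub).mean(axis=(1, 3)) >= 0.5
            halo &= ~lobe_mask
            template[r0:r1, c0:c1][halo] += cfg.halo_strength


def simulate_micrograph(config: SimulationConfig
                        ) -> tuple[Micrograph, list[GroundTruthRecord]]:
    """Render a synthetic micrograph and return it with per-particle truth.

    Particles are laid out on a square grid of cells 1.25 x the particle
    box so every particle can later be boxed without overlap.  Determinism:
    the config seed spawns one sub-stream per particle plus one for the
    noise field, so records are reproducible under subsetting.
    """
    config.validate()
    cell = config.box_size * 1.25
    centers, (nrows, ncols) = _layout_grid(config.n_particles, cell)
    shape = (int(round(nrows * cell / config.pixel_size)),
             int(round(ncols * cell / config.pixel_size)))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_particles + 1)
    records = []
    template = np.full(shape, config.background, dtype=np.float64)
    for pid in range(config.n_particles):
        rng = np.random.default_rng(children[pid])
        rec = _draw_particle(rng, config, pid, centers[pid])
        records.append(rec)
        _render_particle(template, config, rec)
    if config.noise_sd > 0:
        noise_rng = np.random.default_rng(children[-1])
        template = template + noise_rng.normal(0.0, config.noise_sd, size=shape)
    return Micrograph(template, config.pixel_size, dark_lobes=True), records


# ----------------------------------------------------------- toy atomic models

@dataclass(frozen=True)
class ToyAtomicModel:
    """Pseudo-atomic helix bundle spanning a membrane slab.

    ``atoms`` rows are (x, y, z, vdw_radius, monomer_label), all nm; labels
    are contiguous 1..n_monomers.
    """

    atoms: np.ndarray                 # (n, 5)
    slab_midplane: float = 0.0        # nm
    slab_half_thickness: float = 2.0  # nm

    @property
    def n_monomers(self) -> int:
        return int(self.atoms[:, 4].max())

    def to_pdb(self, path) -> None:
        """Write pseudo-atoms as carbon ATOM records (coordinates nm -> A).

        The toy vdw radii are not representable in PDB; re-reading through
        the element table assigns carbon radii instead.
        """
        lines = []
        for i, (x, y, z, _r, label) in enumerate(self.atoms, start=1):
            chain = chr(ord("A") + (int(label) - 1) % 26)
            lines.append(
                f"ATOM  {i % 100000:5d}  C   ALA {chain}{int(i % 10000):4d}    "
                f"{x * 10:8.3f}{y * 10:8.3f}{z * 10:8.3f}  1.00  0.00           C"
            )
        Path(path).write_text("\n".join(lines) + "\nEND\n")


def _helix_centers(n_helices: int, helix_radius: float, layout: str) -> np.ndarray:
    if layout == "hex":
        # compact bundle: tangent helices on the hexagonal lattice sites
        # nearest the axis, the packing of a real transmembrane domain
        a = 2.0 * helix_radius
        sites = []
        for i in range(-4, 5):
            for j in range(-4, 5):
                x = a * (i + 0.5 * j)
                y = a * (math.sqrt(3) / 2.0) * j
                sites.append((math.hypot(x, y), x, y))
        sites.sort()
        if n_helices > len(sites):
            raise ValueError("too many helices for the hex layout")
        arr = np.asarray([(x, y) for _, x, y in sites[:n_helices]])
        return arr - arr.mean(axis=0)
    if layout == "ring":
        if n_helices == 1:
            return np.zeros((1, 2))
        ring_r = helix_radius / math.sin(math.pi / n_helices)
        t = 2 * np.pi * np.arange(n_helices) / n_helices
        return ring_r * np.stack([np.cos(t), np.sin(t)], axis=1)
    if layout == "grid":
        side = int(math.ceil(math.sqrt(n_helices)))
        pts = [(2 * helix_radius * c, 2 * helix_radius * r)
               for r in range(side) for c in range(side)][:n_helices]
        arr = np.asarray(pts, dtype=float)
        return arr - arr.mean(axis=0)
    raise ValueError(f"unknown bundle_layout {layout!r}")


def make_toy_bundle(n_helices: int,
                    helix_radius: float = 0.7463,
                    bundle_layout: str = "hex",
                    n_monomers: int = 1,
                    monomer_spacing: float | None = None,
                    slab_half_thickness: float = 2.0) -> ToyAtomicModel:
    """Build a toy transmembrane helix bundle of pseudo-atoms.

    Each helix is a vertical column of pseudo-atoms (spacing = vdw radius)
    spanning the slab.  The default helix radius gives a per-helix membrane
    footprint of ~1.75 nm^2, so an 8-helix monomer occupies ~14 nm^2 — a
    realistic packing density for a transmembrane domain.  Monomer copies
    are offset along x without overlap unless ``monomer_spacing`` forces it.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    if helix_radius <= 0:
        raise ValueError("helix_radius must be positive")
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    centers = _helix_centers(n_helices, helix_radius, bundle_layout)
    if len(centers) > 1:
        d = np.hypot(*(centers[:, None, :] - centers[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise PackingError("bundle layout places helices coincident")
    bound = np.hypot(*centers.T).max() + helix_radius
    if monomer_spacing is None:
        monomer_spacing = 2.0 * bound * 1.05
    h = slab_half_thickness
    n_z = max(2, int(math.ceil(2 * h / helix_radius)) + 1)
    zs = np.linspace(-h, h, n_z)
    atoms = []
    for m in range(n_monomers):
        ox = m * monomer_spacing
        for cx, cy in centers:
            for z in zs:
                atoms.append((cx + ox, cy, z, helix_radius, m + 1))
    return ToyAtomicModel(np.asarray(atoms, dtype=float),
                          slab_midplane=0.0, slab_half_thickness=h)


# -------------------------------------------------------------------- I/O

def ground_truth_to_tsv(records: list[GroundTruthRecord], path) -> None:
    """One row per lobe, TSV with header."""
    rows = []
    for rec in records:
        for k, lobe in enumerate(rec.lobes):
            rows.append({
                "particle_id": rec.particle_id,
                "center_x_nm": rec.center[0],
                "center_y_nm": rec.center[1],
                "n_lobes": rec.n_lobes,
                "lobe_index": k,
                "lobe_x_nm": lobe.centroid[0],
                "lobe_y_nm": lobe.centroid[1],
                "lobe_area_nm2": lobe.area,
                "shape_class": lobe.shape_class,
                "orientation_deg": lobe.orientation_deg,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def ground_truth_from_tsv(path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for pid, grp in df.groupby("particle_id", sort=True):
        lobes = tuple(
            LobeTruth((r.lobe_x_nm, r.lobe_y_nm), r.lobe_area_nm2,
                      r.shape_class, r.orientation_deg)
            for r in grp.sort_values("lobe_index").itertuples()
        )
        first = grp.iloc[0]
        records.append(GroundTruthRecord(int(pid),
                                         (first.center_x_nm, first.center_y_nm),
                                         lobes))
    return records
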