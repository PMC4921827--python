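"""Inference stage: footprint areas vs imaged lobe geometry, and the
per-lobe stoichiometry call, plus end-to-end pipeline orchestration.

The stoichiometry logic is deliberately plain: given a table of oligomer
cross-sectional areas A_n (n = 2..6) and the imaged mean lobe area, the
called oligomer order is the argmin of |A_n - mean| (ties to the smaller
n, a conservative reading), and the synthase count per rosette is six
times that order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from . import footprint as fp
from . import lobeshape, metrology, reference, synthgen
from .classavg import (align_stack, classify_stable, extract_boxes,
                       invert_contrast, pick_lobes)
from .io import Micrograph, write_stack_tiff, write_tiff

logger = logging.getLogger(__name__)

__all__ = [
    "percent_excess",
    "stoichiometry_call",
    "StoichiometryCall",
    "overlay_fit",
    "OverlayFit",
    "published_comparisons",
    "run_pipeline",
    "PipelineStageError",
    "ComparisonReport",
]


def percent_excess(a: float, b: float) -> float:
    """How much larger ``a`` is than ``b``, in percent of ``b``."""
    if b <= 0:
        raise ValueError("percent_excess reference must be positive")
    return 100.0 * (a - b) / b


@dataclass(frozen=True)
class StoichiometryCall:
    """Result of matching oligomer areas to the imaged mean lobe area."""

    best_order: int
    cesa_count: int                 # 6 lobes x best order
    mean_lobe_area: float           # nm^2
    areas: dict                     # order -> nm^2
    deviations_pct: dict            # order -> percent excess over mean area


def stoichiometry_call(areas: dict, mean_lobe_area: float,
                       orders=range(2, 7)) -> StoichiometryCall:
    """Call the per-lobe oligomer order from a footprint-area table.

    ``areas`` maps oligomer order to cross-sectional area (nm^2); missing
    orders are excluded with a warning.  Ties in |A_n - mean| go to the
    smaller order.
    """
    if mean_lobe_area <= 0:
        raise ValueError("mean lobe area must be positive")
    present = {}
    for n in orders:
        if n in areas:
            present[int(n)] = float(areas[n])
        else:
            warnings.warn(f"oligomer order {n} missing from area table; excluded")
    if not present:
        raise ValueError("no oligomer areas to compare")
    best = min(sorted(present), key=lambda n: (abs(present[n] - mean_lobe_area), n))
    deviations = {n: percent_excess(a, mean_lobe_area) for n, a in present.items()}
    return StoichiometryCall(best, 6 * best, mean_lobe_area, present, deviations)


# ---------------------------------------------------------------- overlay

@dataclass(frozen=True)
class OverlayFit:
    """Fit of an assembly footprint over a class-average lobe mask."""

    coverage: float        # area(footprint & mask) / area(mask)
    spill: float           # area(footprint \\ mask) / area(footprint)
    clash_area: float      # inter-lobe footprint overlap, nm^2
    rotation_deg: float    # global rotation applied to the footprint
    mask_area_nm2: float
    footprint_area_nm2: float


def _footprint_mask(disks: fp.DiskSet, shape, pixel_size: float,
                    center_nm, rotation_deg: float) -> np.ndarray:
    d = disks.recentered().rotated(rotation_deg).translated(*center_nm)
    rows, cols = shape
    out = np.zeros(shape, dtype=bool)
    for cx, cy, r in zip(d.x, d.y, d.r):
        j0 = max(0, int((cx - r) / pixel_size) - 1)
        j1 = min(cols, int((cx + r) / pixel_size) + 2)
        i0 = max(0, int((cy - r) / pixel_size) - 1)
        i1 = min(rows, int((cy + r) / pixel_size) + 2)
        if i1 <= i0 or j1 <= j0:
            continue
        ys = (np.arange(i0, i1) + 0.5) * pixel_size
        xs = (np.arange(j0, j1) + 0.5) * pixel_size
        out[i0:i1, j0:j1] |= ((ys - cy)[:, None] ** 2
                              + (xs - cx)[None, :] ** 2) <= r * r
    return out


def _smooth_mask(mask: np.ndarray, fwhm_px: float) -> np.ndarray:
    """Blur a boolean raster and re-threshold preserving its pixel count.

    Mirrors the resolution-blurred isosurface rendering used for the
    published overlays: the footprint keeps its van der Waals area but
    its outline becomes a compact envelope instead of a disk clover.
    """
    from scipy import ndimage as _ndi

    if fwhm_px <= 0:
        return mask
    sigma = fwhm_px * fp.FWHM_TO_SIGMA
    blurred = _ndi.gaussian_filter(mask.astype(float), sigma)
    k = int(mask.sum())
    flat = np.sort(blurred.ravel())[::-1]
    return blurred >= flat[min(k, flat.size) - 1]


def overlay_fit(assembly: fp.DiskSet, class_average: np.ndarray,
                pixel_size: float, rotation_step_deg: float = 1.0,
                blur_fwhm: float = 2.5) -> OverlayFit:
    """Overlay an assembly footprint on a class-average image.

    The lobe mask is the Otsu superlevel set of the (bright-lobe) class
    average.  The footprint is centred on the mask centroid, rendered as
    an area-preserving envelope blurred to ``blur_fwhm`` nm (0 disables
    the smoothing), and the global rotation is optimized in 1-degree
    steps to maximize coverage.
    """
    img = np.asarray(class_average, dtype=float)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(assembly) == 0:
        raise ValueError("empty footprint")
    extent = min(img.shape) * pixel_size
    if 2.0 * assembly.recentered().bounding_radius > 2.0 * extent:
        raise ValueError("scale mismatch: footprint far exceeds the image extent")
    mask = img >= threshold_otsu(img)
    if not mask.any():
        raise ValueError("class average has no foreground above threshold")
    ys, xs = np.nonzero(mask)
    center = ((xs.mean() + 0.5) * pixel_size, (ys.mean() + 0.5) * pixel_size)
    mask_area = float(mask.sum()) * pixel_size ** 2

    best = None
    for rot in np.arange(0.0, 360.0, rotation_step_deg):
        fmask = _footprint_mask(assembly, img.shape, pixel_size, center, rot)
        if fmask.sum() == 0:
            raise ValueError("footprint rasterized to zero pixels (scale mismatch?)")
        fmask = _smooth_mask(fmask, blur_fwhm / pixel_size)
        fsum = fmask.sum()
        cov = float((fmask & mask).sum()) / float(mask.sum())
        if best is None or cov > best[0]:
            spill = float((fmask & ~mask).sum()) / float(fsum)
            best = (cov, spill, float(rot), float(fsum) * pixel_size ** 2)
    cov, spill, rot, fp_area = best
    clash = 0.0
    labels = np.unique(assembly.label)
    if len(labels) > 1:
        subs = [fp.DiskSet(assembly.x[assembly.label == l], assembly.y[assembly.label == l],
                           assembly.r[assembly.label == l], assembly.label[assembly.label == l])
                for l in labels]
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                clash += fp.pair_overlap_area(subs[i], subs[j])
    return OverlayFit(cov, spill, clash, rot, mask_area, fp_area)


# ------------------------------------------------- published worked examples

def published_comparisons() -> dict:
    """Recompute the worked-example arithmetic from the packaged inputs.

    Every number here is derived at call time from the published input
    tables: summary means of means, the circular-vs-hexagonal perimeter
    excess, the class-average vs original diameter offset, the
    stoichiometry calls for both transmembrane models, and the cytosolic
    diameter comparisons (the normalization-ambiguous negative-stain
    comparison is reported under both conventions).
    """
    dims = reference.dimension_table()
    cols = {"perimeter": "perimeter_nm", "diameter": "diameter_nm",
            "lobe_area": "lobe_area_nm2"}
    groups = {}
    for sg, sub in dims.groupby("supergroup", sort=False):
        groups[sg] = {k: sub[c].dropna().tolist() for k, c in cols.items()}
    table = metrology.summarize(groups)
    overall = {k: float(table.overall[f"{k}_mean"]) for k in cols}
    per_group = {g: {k: float(table.per_group.loc[g, f"{k}_mean"]) for k in cols}
                 for g in table.per_group.index}

    orig = dims[dims["group"] == "original"].set_index("geometry")
    p_circ = float(orig.loc["circle", "perimeter_nm"])
    p_hex = float(orig.loc["hexagon", "perimeter_nm"])

    calls = {model: stoichiometry_call(reference.oligomer_areas(model),
                                       overall["lobe_area"])
             for model in ("8tmh", "7tmh_cesa")}

    sc = reference.published_scalars()
    d_sixfold = sc["cytosolic_diameter_sixfold_trimer_nm"]
    d_saxs = sc["cytosolic_diameter_saxs_schematic_nm"]
    d_cyt_avg = (d_sixfold + d_saxs) / 2.0
    a_img = sc["negstain_trimer_area_nm2"]
    a_comp = sc["computational_cytosolic_trimer_area_nm2"]
    a_saxs = sc["saxs_trimer_area_nm2"]

    return {
        "overall_means": overall,
        "group_means": per_group,
        "perimeter_circle_minus_hexagon_nm": p_circ - p_hex,
        "perimeter_circle_vs_hexagon_excess_pct": percent_excess(p_circ, p_hex),
        "diameter_class_avg_minus_original_nm":
            per_group["class_averages"]["diameter"] - per_group["original"]["diameter"],
        "stoichiometry": {m: c for m, c in calls.items()},
        "trimer_area_excess_pct": {
            m: calls[m].deviations_pct[3] for m in calls},
        "cytosolic_diameter_avg_nm": d_cyt_avg,
        "sixfold_cytosolic_vs_saxs_schematic_excess_pct":
            percent_excess(d_sixfold, d_saxs),
        "cytosolic_vs_membrane_diameter_excess_pct":
            percent_excess(d_cyt_avg, overall["diameter"]),
        # negative-stain trimer vs the two cytosolic models; the published
        # range endpoints use different denominators, so report both
        # conventions for each comparison
        "negstain_vs_computational_excess_pct_of_model":
            percent_excess(a_img, a_comp),
        "negstain_vs_computational_excess_pct_of_image":
            100.0 * (a_img - a_comp) / a_img,
        "negstain_vs_saxs_excess_pct_of_model": percent_excess(a_img, a_saxs),
        "negstain_vs_saxs_excess_pct_of_image": 100.0 * (a_img - a_saxs) / a_img,
    }


# ---------------------------------------------------------------- pipeline

class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ComparisonReport:
    """Everything the comparison stage concludes, with provenance."""

    seed: int
    config_hash: str
    version: str
    n_particles: int
    n_measured: int
    n_excluded: int
    imaged_mean_lobe_area_nm2: float
    imaged_lobe_area_sd_nm2: float
    mean_opposite_spacing_nm: float
    mean_d_circ_nm: float
    mean_d_hex_nm: float
    perimeter_circle_vs_hexagon_excess_pct: float
    toy_oligomer_areas_nm2: dict
    toy_call: StoichiometryCall
    published: dict
    overlay: OverlayFit | None
    class_stability: list[float]
    triangular_fraction_at_zero: float
    median_vertex_offset_deg: float

    def to_json(self, path=None) -> str:
        def default(o):
            if isinstance(o, (StoichiometryCall, OverlayFit)):
                return asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        text = json.dumps(asdict(self), indent=2, sort_keys=True, default=default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _config_hash(cfg: synthgen.SimulationConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config, outdir, K: int = 6, n_trials: int = 5,
                 lobe_box: float = 10.3, contact_tolerance: float = 0.01,
                 oligomer_phase_step_deg: float = 5.0,
                 align_iters: int = 5) -> ComparisonReport:
    """Run simulate -> measure -> average -> score-lobes -> footprint ->
    compare, writing every intermediate into ``outdir``.

    ``config`` is a :class:`~cscmorph.synthgen.SimulationConfig` or a
    mapping of its fields; a mapping without an explicit ``seed`` is
    rejected before any computation (reproducibility contract).
    """
    from dataclasses import asdict as _as

    if isinstance(config, dict):
        if "seed" not in config:
            raise ValueError("pipeline config must specify a seed")
        config = synthgen.SimulationConfig(**config)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        stage("simulate")
        micrograph, records = synthgen.simulate_micrograph(config)
        write_tiff(micrograph, outdir / "micrograph.tif")
        synthgen.ground_truth_to_tsv(records, outdir / "ground_truth.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("simulate", e) from e

    try:
        stage("measure")
        polys = {r.particle_id: [synthgen.lobe_outline(l) for l in r.lobes]
                 for r in records}
        measurements, excluded = metrology.measure_cohort(polys)
        metrology.measurements_to_tsv(measurements, outdir / "measurements.tsv")
        areas = np.concatenate([m.lobe_areas for m in measurements])
        spacing = float(np.mean([m.mean_opposite_spacing for m in measurements]))
        mean_p_circ = float(np.mean([m.P_circ for m in measurements]))
        mean_p_hex = float(np.mean([m.P_hex for m in measurements]))
        summary = metrology.summarize(pd.DataFrame({
            "group": "synthetic",
            "perimeter": [m.P_circ for m in measurements],
            "diameter": [m.d_circ for m in measurements],
            "lobe_area": [m.mean_lobe_area for m in measurements]}))
        summary.per_group.to_csv(outdir / "summary.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("measure", e) from e

    try:
        stage("average")
        centers = [r.center for r in records]
        stack, _ = extract_boxes(micrograph, centers, config.box_size)
        stack = invert_contrast(stack)
        aligned = align_stack(stack, n_iter=align_iters, seed=config.seed)
        classes = classify_stable(aligned, K=min(K, len(aligned.stack)),
                                  n_trials=n_trials, seed=config.seed)
        write_stack_tiff(np.nan_to_num(classes.averages), config.pixel_size,
                         outdir / "class_averages.tif")
        pd.DataFrame({"assignment": classes.assignments,
                      "rotation_deg": classes.rotations_deg,
                      "shift_x_nm": classes.shifts_nm[:, 0],
                      "shift_y_nm": classes.shifts_nm[:, 1]}
                     ).to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("average", e) from e

    try:
        stage("score-lobes")
        inv_micro = Micrograph((micrograph.data.max() + micrograph.data.min())
                               - micrograph.data, config.pixel_size,
                               dark_lobes=False)
        lobe_centers, directions = [], []
        for r in records:
            for l in r.lobes:
                lobe_centers.append(l.centroid)
                d = np.asarray(r.center) - np.asarray(l.centroid)
                directions.append(math.degrees(math.atan2(d[1], d[0])))
        lobes_stack, skipped = pick_lobes(inv_micro, lobe_centers, lobe_box)
        kept_dirs = [d for i, d in enumerate(directions) if i not in set(skipped)]
        scores = []
        for img, cdir in zip(lobes_stack.images, kept_dirs):
            try:
                mask = lobeshape.lobe_mask(img)
                scores.append(lobeshape.triangularity(mask, config.pixel_size,
                                                      center_direction_deg=cdir))
            except ValueError:
                continue
        curve = lobeshape.triangular_fraction(scores)
        curve.to_csv(outdir / "triangular_fraction.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(s) for s in scores]).to_csv(
            outdir / "lobe_scores.tsv", sep="\t", index=False)
        frac0 = float(curve.loc[np.isclose(curve["threshold"], 0.0),
                                "fraction"].iloc[0])
        offsets = np.array([s.vertex_to_center_deg for s in scores
                            if s.triangularity > 0 and np.isfinite(s.vertex_to_center_deg)])
        median_offset = float(np.median(np.abs(offsets))) if offsets.size else float("nan")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("score-lobes", e) from e

    try:
        stage("footprint")
        monomer = fp.project_slab(synthgen.make_toy_bundle(8))
        toy_areas = {}
        oligomers = {}
        for n in range(2, 7):
            olig, _layout = fp.build_cn_oligomer(
                monomer, n, contact_tolerance=contact_tolerance,
                phase_step_deg=oligomer_phase_step_deg)
            oligomers[n] = olig
            toy_areas[n] = fp.union_area(olig)
        pd.DataFrame({"order": list(toy_areas), "area_nm2": list(toy_areas.values())}
                     ).to_csv(outdir / "oligomer_areas.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("footprint", e) from e

    try:
        stage("compare")
        mean_area = float(areas.mean())
        call = stoichiometry_call(toy_areas, mean_area)
        assembly, _ = fp.build_sixfold_assembly(oligomers[call.best_order],
                                                r_ring=spacing / 2.0)
        overlay = None
        retained_idx = [k for k in range(len(classes.stability)) if classes.retained[k]
                        and np.isfinite(classes.averages[k]).all()]
        if retained_idx:
            best_k = max(retained_idx, key=lambda k: classes.stability[k])
            overlay = overlay_fit(assembly, classes.averages[best_k],
                                  config.pixel_size, rotation_step_deg=5.0)
        report = ComparisonReport(
            seed=config.seed,
            config_hash=_config_hash(config),
            version=_package_version(),
            n_particles=config.n_particles,
            n_measured=len(measurements),
            n_excluded=len(excluded),
            imaged_mean_lobe_area_nm2=mean_area,
            imaged_lobe_area_sd_nm2=float(areas.std(ddof=1)),
            mean_opposite_spacing_nm=spacing,
            mean_d_circ_nm=mean_p_circ / math.pi,
            mean_d_hex_nm=metrology.HEX_ACROSS_FLATS * mean_p_hex,
            perimeter_circle_vs_hexagon_excess_pct=percent_excess(mean_p_circ,
                                                                  mean_p_hex),
            toy_oligomer_areas_nm2=toy_areas,
            toy_call=call,
            published=published_comparisons(),
            overlay=overlay,
            class_stability=[float(s) for s in classes.stability],
            triangular_fraction_at_zero=frac0,
            median_vertex_offset_deg=median_offset,
        )
        report.to_json(outdir / "report.json")
        _report_tsv(report, outdir / "report.tsv")
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("compare", e) from e
    return report


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version
    try:
        return version("cscmorph")
    except PackageNotFoundError:
        return "unknown"


def _report_tsv(report: ComparisonReport, path) -> None:
    rows = [
        ("imaged_mean_lobe_area_nm2", round(report.imaged_mean_lobe_area_nm2, 1)),
        ("imaged_lobe_area_sd_nm2", round(report.imaged_lobe_area_sd_nm2, 1)),
        ("mean_opposite_spacing_nm", round(report.mean_opposite_spacing_nm, 1)),
        ("mean_d_circ_nm", round(report.mean_d_circ_nm, 1)),
        ("mean_d_hex_nm", round(report.mean_d_hex_nm, 1)),
        ("best_oligomer_order", report.toy_call.best_order),
        ("cesa_count", report.toy_call.cesa_count),
        ("triangular_fraction_at_zero", round(report.triangular_fraction_at_zero, 2)),
    ]
    for n, a in report.toy_oligomer_areas_nm2.items():
        rows.append((f"toy_oligomer_area_n{n}_nm2", round(a, 1)))
    if report.overlay is not None:
        rows += [("overlay_coverage", round(report.overlay.coverage, 3)),
                 ("overlay_spill", round(report.overlay.spill, 3)),
                 ("overlay_clash_nm2", round(report.overlay.clash_area, 2))]
    pd.DataFrame(rows, columns=["quantity", "value"]).to_csv(path, sep="\t",
                                                             index=False)
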