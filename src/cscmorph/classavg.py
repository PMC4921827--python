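"""Reference-free 2D alignment, classification and class averaging.

This is an in-package stand-in for the single-particle averaging programs
used on rosette CSC images (EMAN2 / RELION / ISAC-style workflows):

* images are black/white inverted so particles are bright, the convention
  of the averaging software;
* alignment is iterative: the reference starts as the unaligned average;
  each round every image is rotationally aligned to the reference by
  polar-resampled circular cross-correlation and translationally by a
  correlation peak, and the reference is re-averaged;
* classification is k-means on intensity-normalized aligned pixel vectors,
  repeated over several sub-seeded trials; a class is retained only when
  its membership is reproducible across trials (mean Jaccard overlap of
  matched classes >= ``min_overlap``), the stability idea behind ISAC's
  "reproducible class averages".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate_image, warp_polar
from sklearn.cluster import KMeans

from .io import Micrograph

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleStack",
    "AlignmentResult",
    "ClassAverageSet",
    "invert_contrast",
    "align_stack",
    "classify_stable",
    "pick_lobes",
    "extract_boxes",
    "odd_box_pixels",
]

DEFAULT_SEED = 20160627


@dataclass
class ParticleStack:
    """Boxed, co-scaled sub-images with source coordinates."""

    images: np.ndarray          # (N, H, W) float
    pixel_size: float           # nm / pixel
    box_size: float             # nm (nominal; pixel box is the nearest odd count)
    coords: np.ndarray | None = None   # (N, 2) source centres, nm
    dark_lobes: bool = True

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("stack images must be (N, H, W)")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("boxes must be square")

    def __len__(self) -> int:
        return self.images.shape[0]


def odd_box_pixels(box_nm: float, pixel_size: float) -> int:
    """Nearest odd pixel count for a box size in nm (boxes get a centre pixel)."""
    exact = box_nm / pixel_size
    k = int(round(exact))
    if k % 2 == 1:
        n = k
    else:
        n = k - 1 if abs(k - 1 - exact) < abs(k + 1 - exact) else k + 1
    return max(1, n)


def extract_boxes(micrograph: Micrograph, centers_nm, box_nm: float
                  ) -> tuple[ParticleStack, list[int]]:
    """Cut square boxes around nm centres; out-of-bounds boxes are skipped
    and logged.  Returns (stack, indices of skipped centres)."""
    px = micrograph.pixel_size
    n = odd_box_pixels(box_nm, px)
    half = n // 2
    rows, cols = micrograph.shape
    images, kept, skipped = [], [], []
    centers_nm = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    for i, (x, y) in enumerate(centers_nm):
        c = int(round(x / px - 0.5))
        r = int(round(y / px - 0.5))
        if r - half < 0 or c - half < 0 or r + half + 1 > rows or c + half + 1 > cols:
            logger.info("box %d at (%.1f, %.1f) nm exceeds image bounds; skipped", i, x, y)
            skipped.append(i)
            continue
        images.append(micrograph.data[r - half:r + half + 1, c - half:c + half + 1])
        kept.append((x, y))
    if not images:
        raise ValueError("no boxes inside image bounds")
    return ParticleStack(np.stack(images), px, box_nm, np.asarray(kept),
                         micrograph.dark_lobes), skipped


def pick_lobes(source, lobe_centers_nm, lobe_box: float = 10.3
               ) -> tuple[ParticleStack, list[int]]:
    """Box individual lobes (default 10.3 nm boxes) from a micrograph.

    A thin wrapper over :func:`extract_boxes` that names the published
    lobe-picking step; boxes exceeding the image boundary are skipped and
    logged.
    """
    if not isinstance(source, Micrograph):
        raise TypeError("pick_lobes expects a Micrograph")
    return extract_boxes(source, lobe_centers_nm, lobe_box)


def invert_contrast(stack: ParticleStack) -> ParticleStack:
    """Map intensities by (max + min - I) over the whole stack.

    An involution: applying twice returns the original stack exactly.
    """
    lo = float(stack.images.min())
    hi = float(stack.images.max())
    return replace(stack, images=(hi + lo) - stack.images,
                   dark_lobes=not stack.dark_lobes)


# ------------------------------------------------------------- alignment

@dataclass
class AlignmentResult:
    """Aligned stack plus per-image transforms.

    ``rotations_deg[i]`` and ``shifts_nm[i]`` map original image i onto the
    final reference (rotate about the box centre, then translate).
    """

    stack: ParticleStack
    rotations_deg: np.ndarray     # (N,), in [0, 360)
    shifts_nm: np.ndarray         # (N, 2) as (dx, dy) nm
    excluded: list[int]
    objective_history: list[float]   # mean correlation to reference per iteration
    reference: np.ndarray


def _polar(image: np.ndarray, n_angles: int, radius: float) -> np.ndarray:
    p = warp_polar(image, radius=radius, output_shape=(n_angles, int(radius)))
    return p - p.mean()


def _estimate_rotation(polar_img: np.ndarray, polar_ref: np.ndarray,
                       step_deg: float) -> float:
    """Rotation (deg) that brings the image onto the reference."""
    fi = np.fft.rfft(polar_img, axis=0)
    fr = np.fft.rfft(polar_ref, axis=0)
    corr = np.fft.irfft(np.conj(fi) * fr, n=polar_img.shape[0], axis=0).sum(axis=1)
    k = int(np.argmax(corr))
    # polar row k of the image matches row 0 of the reference: the image is
    # rotated by -k*step relative to the reference in warp_polar's angle
    # convention, which matches skimage.rotate's CCW angle.
    return (-k * step_deg) % 360.0


def _apply_transform(image: np.ndarray, angle_deg: float, shift_px) -> np.ndarray:
    out = _rotate_image(image, angle_deg, preserve_range=True, order=1,
                        mode="constant", cval=float(image.mean()))
    return ndimage.shift(out, (shift_px[0], shift_px[1]), order=1,
                         mode="constant", cval=float(image.mean()))


def align_stack(stack: ParticleStack, n_iter: int = 8, angle_step: float = 1.0,
                max_shift_frac: float = 0.25, seed: int = DEFAULT_SEED
                ) -> AlignmentResult:
    """Iterative reference-free alignment of a particle stack.

    Stops after ``n_iter`` rounds or when the median change in shift drops
    below 0.1 pixel.  Zero-variance (blank) images are excluded with a
    warning.  Each round re-transforms the *original* images so
    interpolation error does not accumulate.
    """
    if len(stack) < 2:
        raise ValueError("alignment requires at least 2 images")
    variances = stack.images.var(axis=(1, 2))
    excluded = [int(i) for i in np.flatnonzero(variances < 1e-15)]
    for i in excluded:
        logger.warning("image %d has zero variance; excluded from alignment", i)
    idx = [i for i in range(len(stack)) if i not in excluded]
    imgs = stack.images[idx]
    n, h, _ = imgs.shape
    n_angles = max(8, int(round(360.0 / angle_step)))
    step = 360.0 / n_angles
    radius = h / 2.0 - 1.0
    max_shift = max_shift_frac * h

    angles = np.zeros(n)
    shifts = np.zeros((n, 2))   # (row, col) px
    aligned = imgs.copy()
    reference = aligned.mean(axis=0)
    history: list[float] = []
    prev_shifts = shifts.copy()
    for _ in range(n_iter):
        polar_ref = _polar(reference, n_angles, radius)
        for i in range(n):
            ang = _estimate_rotation(_polar(imgs[i], n_angles, radius),
                                     polar_ref, step)
            rotated = _rotate_image(imgs[i], ang, preserve_range=True, order=1,
                                    mode="constant", cval=float(imgs[i].mean()))
            sh, _, _ = phase_cross_correlation(reference, rotated,
                                               upsample_factor=10,
                                               normalization=None)
            sh = np.clip(sh, -max_shift, max_shift)
            angles[i] = ang
            shifts[i] = sh
            aligned[i] = _apply_transform(imgs[i], ang, sh)
        reference = aligned.mean(axis=0)
        flat_ref = (reference - reference.mean()).ravel()
        denom = np.linalg.norm(flat_ref)
        corrs = []
        for i in range(n):
            flat = (aligned[i] - aligned[i].mean()).ravel()
            nrm = np.linalg.norm(flat)
            corrs.append(float(flat @ flat_ref / (nrm * denom)) if nrm > 0 else 0.0)
        history.append(float(np.mean(corrs)))
        delta = np.hypot(*(shifts - prev_shifts).T)
        prev_shifts = shifts.copy()
        if np.median(delta) < 0.1 and len(history) > 1:
            break

    out_images = np.zeros_like(stack.images)
    out_images[idx] = aligned
    rot_full = np.zeros(len(stack))
    shift_full = np.zeros((len(stack), 2))
    rot_full[idx] = angles % 360.0
    # (row, col) px -> (dx, dy) nm
    shift_full[idx] = shifts[:, ::-1] * stack.pixel_size
    kept_stack = replace(stack, images=out_images[idx],
                         coords=None if stack.coords is None else stack.coords[idx])
    return AlignmentResult(kept_stack, rot_full[idx], shift_full[idx],
                           excluded, history, reference)


# --------------------------------------------------------- classification

@dataclass
class ClassAverageSet:
    """K class averages with assignments, transforms and stability scores.

    ``assignments[i] == -1`` marks a particle left unassigned because its
    class failed the stability filter.
    """

    averages: np.ndarray          # (K, H, W); NaN panes for unstable classes
    assignments: np.ndarray       # (N,)
    rotations_deg: np.ndarray | None
    shifts_nm: np.ndarray | None
    stability: np.ndarray         # (K,)
    retained: np.ndarray          # (K,) bool
    pixel_size: float

    @property
    def class_sizes(self) -> np.ndarray:
        return np.array([(self.assignments == k).sum()
                         for k in range(len(self.stability))])


def _jaccard_matrix(labels_a: np.ndarray, labels_b: np.ndarray, k: int) -> np.ndarray:
    m = np.zeros((k, k))
    for i in range(k):
        a = labels_a == i
        for j in range(k):
            b = labels_b == j
            union = (a | b).sum()
            m[i, j] = (a & b).sum() / union if union else 0.0
    return m


def classify_stable(alignment: AlignmentResult | ParticleStack, K: int = 6,
                    n_trials: int = 5, min_overlap: float = 0.5,
                    seed: int = DEFAULT_SEED) -> ClassAverageSet:
    """Stability-filtered k-means classification of aligned images.

    k-means runs ``n_trials`` times with different sub-seeds on
    zero-mean/unit-SD pixel vectors.  Trials are matched to the first trial
    by Hungarian assignment on the Jaccard matrix; a class is retained when
    the mean Jaccard of its matched classes is >= ``min_overlap``.  With a
    single trial every class passes (degenerate case).  Class averages are
    computed from the unnormalized aligned images of retained members.
    """
    if isinstance(alignment, AlignmentResult):
        stack = alignment.stack
        rotations, shifts = alignment.rotations_deg, alignment.shifts_nm
    else:
        stack, rotations, shifts = alignment, None, None
    if K < 1 or n_trials < 1:
        raise ValueError("K and n_trials must be >= 1")
    n = len(stack)
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} images in the stack")
    flat = stack.images.reshape(n, -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (flat - mu) / sd

    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_trials)]
    labelings = [KMeans(n_clusters=K, n_init=4, random_state=s).fit_predict(X)
                 for s in sub]
    base = labelings[0]
    stability = np.ones(K)
    if n_trials > 1:
        scores = np.zeros((n_trials - 1, K))
        for t, lab in enumerate(labelings[1:]):
            m = _jaccard_matrix(base, lab, K)
            ri, ci = linear_sum_assignment(-m)
            scores[t, ri] = m[ri, ci]
        stability = scores.mean(axis=0)
    retained = stability >= min_overlap
    assignments = np.where(retained[base], base, -1)

    averages = np.full((K,) + stack.images.shape[1:], np.nan)
    for k in range(K):
        members = assignments == k
        if members.any():
            averages[k] = stack.images[members].mean(axis=0)
    return ClassAverageSet(averages, assignments, rotations, shifts,
                           stability, retained, stack.pixel_size)
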