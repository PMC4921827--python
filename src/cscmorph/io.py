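"""Raster containers and plain-file I/O shared across the pipeline.

All physical coordinates are in nanometres.  A raster pixel ``(row, col)``
maps to the nm plane through its centre: ``x = (col + 0.5) * pixel_size``,
``y = (row + 0.5) * pixel_size``, origin at the top-left corner, y
increasing downward (image convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: fixed intensity window used when quantizing float rasters to 16-bit TIFF
TIFF_INTENSITY_RANGE = (0.0, 2.0)


@dataclass
class Micrograph:
    """A 2-D intensity raster with a physical scale.

    Parameters
    ----------
    data : (rows, cols) float array
        Intensities.  Freeze-fracture replica polarity renders particles
        *dark* on a lighter membrane background.
    pixel_size : float
        Sampling in nm/pixel.
    dark_lobes : bool
        Contrast polarity flag: True for raw replica polarity (dark
        particles), False after black/white inversion.
    """

    data: np.ndarray
    pixel_size: float
    dark_lobes: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("micrograph data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(width, height) of the field of view in nm."""
        return (self.shape[1] * self.pixel_size, self.shape[0] * self.pixel_size)

    def copy(self) -> "Micrograph":
        return replace(self, data=self.data.copy())


def pixel_centers(shape: tuple[int, int], pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(x, y)`` nm coordinate arrays of the pixel centres.

    ``x`` has shape (cols,), ``y`` shape (rows,).
    """
    rows, cols = shape
    x = (np.arange(cols) + 0.5) * pixel_size
    y = (np.arange(rows) + 0.5) * pixel_size
    return x, y


def nm_to_index(xy: np.ndarray, pixel_size: float) -> np.ndarray:
    """Map nm points to the nearest (row, col) pixel index."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    col = np.round(xy[:, 0] / pixel_size - 0.5).astype(int)
    row = np.round(xy[:, 1] / pixel_size - 0.5).astype(int)
    return np.stack([row, col], axis=1)


def _quantize(data: np.ndarray) -> np.ndarray:
    lo, hi = TIFF_INTENSITY_RANGE
    scaled = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return np.round(scaled * np.iinfo(np.uint16).max).astype(np.uint16)


def _dequantize(data: np.ndarray) -> np.ndarray:
    lo, hi = TIFF_INTENSITY_RANGE
    return lo + data.astype(np.float64) / np.iinfo(np.uint16).max * (hi - lo)


def write_tiff(micrograph: Micrograph, path) -> None:
    """Write a micrograph as 16-bit TIFF with nm/pixel in the resolution tag."""
    px_per_cm = 1.0e7 / micrograph.pixel_size
    tifffile.imwrite(
        path,
        _quantize(micrograph.data),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_nm": micrograph.pixel_size,
                  "dark_lobes": bool(micrograph.dark_lobes)},
    )


def read_tiff(path) -> Micrograph:
    """Read a micrograph written by :func:`write_tiff` (or any TIFF with
    a CENTIMETER resolution tag)."""
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        pixel_size = None
        dark = True
        meta = tf.shaped_metadata or tf.imagej_metadata
        if meta:
            entry = meta[0] if isinstance(meta, (list, tuple)) else meta
            pixel_size = entry.get("pixel_size_nm")
            dark = bool(entry.get("dark_lobes", True))
        if pixel_size is None:
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                pixel_size = 1.0e7 * den / num
        if pixel_size is None:
            raise ValueError(f"{path}: no pixel-size metadata found")
    if data.dtype == np.uint16:
        data = _dequantize(data)
    return Micrograph(data=np.asarray(data, dtype=np.float64),
                      pixel_size=float(pixel_size), dark_lobes=dark)


def write_stack_tiff(images: np.ndarray, pixel_size: float, path) -> None:
    """Write an (N, H, W) stack as a multi-page 16-bit TIFF."""
    px_per_cm = 1.0e7 / pixel_size
    tifffile.imwrite(
        path,
        _quantize(np.asarray(images)),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
        metadata={"pixel_size_nm": pixel_size},
    )
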