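"""Grid-based threshold-band pixel counting and 16-color pseudocolor rendering.

The grid metric counts the pixels of a fixed rectangular ROI whose gray
values fall inside an inclusive threshold band (70-140 or 70-110 for
ex vivo 55x100 grids; 100-140 for in vivo 55x80 grids). It summarizes
both the mean intensity and the gray-value distribution of the tissue
and is sensitive to the tumor/normal transition zone.

For 2D display, B-scans are pseudocolored with a 16-entry lookup table:
gray bins of width 16 map to hues running black/blue (low signal) through
green (intermediate) to yellow/orange/red (high signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridROI", "ColorLUT", "DEFAULT_LUT16", "grid_count", "colorize_16",
           "auto_roi"]


@dataclass(frozen=True)
class GridROI:
    """A fixed counting grid: top-left corner, size and gray band (inclusive)."""

    top: int
    left: int
    width_cols: int = 55
    height_rows: int = 100
    band: tuple[int, int] = (70, 140)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not 0 <= lo <= hi <= 255:
            raise ValueError("band must satisfy 0 <= lo <= hi <= 255")
        if self.width_cols < 1 or self.height_rows < 1:
            raise ValueError("ROI size must be positive")
        if self.top < 0 or self.left < 0:
            raise ValueError("ROI corner must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.width_cols * self.height_rows


def grid_count(image: np.ndarray, roi: GridROI) -> int:
    """Count ROI pixels whose gray value lies inside the band (inclusive).

    Both band endpoints are included, matching interactive threshold
    semantics of common image software.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    r1 = roi.top + roi.height_rows
    c1 = roi.left + roi.width_cols
    if r1 > img.shape[0] or c1 > img.shape[1]:
        raise ValueError("ROI out of bounds")
    patch = img[roi.top:r1, roi.left:c1]
    lo, hi = roi.band
    return int(np.count_nonzero((patch >= lo) & (patch <= hi)))


def auto_roi(image: np.ndarray, width_cols: int = 55, height_rows: int = 100,
             band: tuple[int, int] = (70, 140),
             surface_threshold: int = 70) -> GridROI:
    """Place a grid ROI along the midline of the specimen's top layer.

    The top row is the median per-column tissue surface index (first
    supra-threshold row after morphological cleanup) and the ROI is
    centered laterally.
    """
    from .volume3d import extract_surface

    img = np.asarray(image)
    surface = extract_surface(img, threshold=surface_threshold)
    defined = surface[np.isfinite(surface)]
    if defined.size == 0:
        raise ValueError("no tissue surface detected")
    top = int(np.median(defined))
    top = min(top, max(img.shape[0] - height_rows, 0))
    left = max((img.shape[1] - width_cols) // 2, 0)
    return GridROI(top=top, left=left, width_cols=width_cols,
                   height_rows=height_rows, band=band)


def _default_table() -> np.ndarray:
    # black -> blue -> green -> yellow -> orange -> red; a documented
    # approximation of the classic 16-color display LUT (no canonical RGB
    # values are published).
    return np.array([
        (0, 0, 0), (32, 0, 96), (0, 0, 160), (0, 64, 224),
        (0, 128, 255), (0, 192, 224), (0, 224, 128), (0, 255, 0),
        (128, 255, 0), (192, 240, 0), (255, 224, 0), (255, 192, 0),
        (255, 144, 0), (255, 96, 0), (255, 32, 0), (255, 0, 0),
    ], dtype=np.uint8)


@dataclass(frozen=True)
class ColorLUT:
    """A 16-entry RGB lookup table over gray bins of width 16."""

    table: np.ndarray = field(default_factory=_default_table)

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.uint8)
        if t.shape != (16, 3):
            raise ValueError("LUT must have exactly 16 RGB entries")
        object.__setattr__(self, "table", t)

    def bin_of(self, gray: int) -> int:
        return int(gray) // 16


DEFAULT_LUT16 = ColorLUT()


def colorize_16(image: np.ndarray, lut: ColorLUT = DEFAULT_LUT16) -> np.ndarray:
    """Map an 8-bit grayscale image to RGB through the 16-color LUT.

    Pixel gray ``g`` maps to ``lut.table[g // 16]`` (pure per-pixel
    function; bins partition [0, 255]).
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        if np.any((img < 0) | (img > 255)):
            raise ValueError("image values must lie in [0, 255]")
        img = img.astype(np.uint8)
    return lut.table[img >> 4]
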