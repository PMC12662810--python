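"""A-line / ROI depth profiles, trendline smoothing and the descending-angle metric.

An A-line plots gray value against imaging depth; averaging a block of
adjacent columns gives an ROI sampling-line profile. Averaging every 10
rows of a profile yields the *trendline*, a smoothed curve whose peak
value and descending slope are stable tissue descriptors: tumor tissue
shows a lower peak and a gentler decline than peritumoral brain.

The descending slope is reported as the angle between the descending
segment of the trendline and the vertical (gray-value) axis after the
plot is normalized to a 4:3 box — depth spans 4 units horizontally and
the full gray range 3 units vertically. Gentle decay (low attenuation)
gives a large angle; steep decay a small one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["DepthProfile", "TrendProfile", "roi_depth_profile", "trendline",
           "descending_angle"]


@dataclass
class DepthProfile:
    """Mean gray value per row over an ROI column band."""

    values: np.ndarray
    row_span: tuple[int, int]      # (first_row, last_row) inclusive
    width_cols: int


@dataclass
class TrendProfile:
    """Block-averaged depth profile with peak bookkeeping."""

    block_means: np.ndarray
    block_size: int
    n_rows: int                    # rows of the underlying profile
    peak_block: int
    peak_value: float
    descent_end_block: Optional[int] = None
    descent_rule: Optional[str] = None    # "threshold" | "minimum"
    angle_deg: Optional[float] = None
    angle_flat: bool = False


def roi_depth_profile(bscan: np.ndarray, col_range: tuple[int, int],
                      row_range: Optional[tuple[int, int]] = None) -> DepthProfile:
    """Mean gray-value profile over columns [col_lo, col_hi) of a B-scan.

    A width-1 column range reproduces the raw A-line.
    """
    img = np.asarray(bscan, dtype=float)
    if img.ndim != 2:
        raise ValueError("B-scan must be 2D")
    c0, c1 = col_range
    r0, r1 = row_range if row_range is not None else (0, img.shape[0])
    if not (0 <= c0 < c1 <= img.shape[1]) or not (0 <= r0 < r1 <= img.shape[0]):
        raise ValueError("empty or out-of-bounds ROI range")
    values = img[r0:r1, c0:c1].mean(axis=1)
    return DepthProfile(values=values, row_span=(r0, r1 - 1), width_cols=c1 - c0)


def trendline(profile, block_size: int = 10) -> TrendProfile:
    """Average a depth profile every ``block_size`` rows.

    Block ``b`` averages rows ``[b*block_size, (b+1)*block_size)``; a
    trailing partial block is averaged over its actual rows. The peak is
    the maximum block mean, ties broken toward the shallow side.
    """
    values = profile.values if isinstance(profile, DepthProfile) else np.asarray(profile, float)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n = values.size
    if n < 2 * block_size:
        raise ValueError("profile too short: need at least 2 complete blocks")
    n_blocks = math.ceil(n / block_size)
    means = np.array([values[b * block_size: (b + 1) * block_size].mean()
                      for b in range(n_blocks)])
    peak_block = int(np.argmax(means))
    return TrendProfile(block_means=means, block_size=block_size, n_rows=n,
                        peak_block=peak_block, peak_value=float(means[peak_block]))


def descending_angle(trend: TrendProfile, aspect: tuple[float, float] = (4.0, 3.0),
                     gray_range: tuple[float, float] = (0.0, 255.0),
                     end_threshold: float = 45.0) -> TrendProfile:
    """Angle of the trendline's descending segment versus the vertical axis.

    The descending segment runs from the peak block to the first
    post-peak block whose mean falls below ``end_threshold`` (matching
    the estimator's stop criterion); if no block qualifies, the post-peak
    minimum is used and flagged in ``descent_rule``. Coordinates are
    normalized so the full block axis spans ``aspect[0]`` horizontal
    units and the full gray range ``aspect[1]`` vertical units; the
    angle is ``atan(dx'/dy')`` in degrees. A flat segment (no gray drop)
    returns 90 degrees with ``angle_flat`` set.

    Returns the trend with the descent fields filled in.
    """
    means = trend.block_means
    peak = trend.peak_block
    if peak >= means.size - 1:
        raise ValueError("no descending segment: peak is the last block")
    tail = means[peak + 1:]
    below = np.flatnonzero(tail < end_threshold)
    if below.size:
        end_block = peak + 1 + int(below[0])
        rule = "threshold"
    else:
        end_block = peak + 1 + int(np.argmin(tail))
        rule = "minimum"
    # normalized coordinates: full axis extents map to the aspect box
    n_blocks_axis = trend.n_rows / trend.block_size   # includes partial block
    g_lo, g_hi = gray_range
    dx = (end_block - peak) / n_blocks_axis * aspect[0]
    dy = (trend.peak_value - means[end_block]) / (g_hi - g_lo) * aspect[1]
    flat = dy <= 0
    angle = 90.0 if flat else math.degrees(math.atan2(dx, dy))
    trend.descent_end_block = end_block
    trend.descent_rule = rule
    trend.angle_deg = float(angle)
    trend.angle_flat = bool(flat)
    return trend
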