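"""Two-point optical attenuation coefficient estimation on OCT A-lines.

The attenuation coefficient of a depth profile is computed from the gray
value at a bright starting row near the tissue surface (``P_i``) and a
dim ending row deeper in the tissue (``P_L``)::

    mu_t = (10 / L) * log10(P_i / P_L),   L = n_rows * axial_pitch_mm

with the axial pitch fixed at 0.024445 mm/row by the system. Values above
11 indicate a strong-reflection noise start point (or a low-gray noise end
point) and are discarded; negative values indicate a high-gray noise end
point and are likewise discarded. Accepted values therefore lie in
[0, 11], numerically the scale of the reported tissue statistics.

Two start rules and two end rules are provided:

* ``fourth_largest`` start (volume pipeline): sort the column, take the
  fourth-largest gray value, robust to up to three specular spikes.
* ``max`` start: the global maximum.
* ``running_mean_lt_45`` end (volume pipeline): slide a 5-pixel window
  down the column; stop at the first window whose mean gray is < 45.
  ``p_end`` is that window mean, and the ending row is the window centre
  (the row whose signal the window mean estimates).
* ``band_40_80`` end (single-measurement mode): the first pixel below the
  start whose gray value lies in [40, 80].
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geometry import AXIAL_PITCH_MM

__all__ = [
    "Status",
    "EstimatorConfig",
    "AttenuationEstimate",
    "BScanEstimates",
    "attenuation_coefficient",
    "find_start_row",
    "find_end_row",
    "estimate_column",
    "estimate_bscan",
]


class Status(str, enum.Enum):
    """Outcome of an attenuation estimate."""

    ACCEPTED = "accepted"
    DISCARDED_HIGH = "discarded_high"          # mu > 11: strong-reflection noise
    DISCARDED_NEGATIVE = "discarded_negative"  # mu < 0: end row brighter than start
    NO_SEGMENT = "no_segment"                  # no valid start/end pair found


@dataclass(frozen=True)
class EstimatorConfig:
    """Tunable parameters of the two-point estimator.

    ``start_rule`` is one of ``"fourth_largest"`` / ``"max"``;
    ``end_rule`` is one of ``"running_mean_lt_45"`` / ``"band_40_80"``.
    """

    axial_pitch_mm: float = AXIAL_PITCH_MM
    start_rule: str = "fourth_largest"
    end_rule: str = "running_mean_lt_45"
    running_window: int = 5
    mean_threshold: float = 45.0
    band_low: float = 40.0
    band_high: float = 80.0
    discard_high: float = 11.0

    def __post_init__(self) -> None:
        if self.start_rule not in ("fourth_largest", "max"):
            raise ValueError(f"unknown start rule {self.start_rule!r}")
        if self.end_rule not in ("running_mean_lt_45", "band_40_80"):
            raise ValueError(f"unknown end rule {self.end_rule!r}")
        if self.running_window < 1:
            raise ValueError("running_window must be >= 1")
        for t in (self.mean_threshold, self.band_low, self.band_high):
            if not 0 <= t <= 255:
                raise ValueError("thresholds must lie in [0, 255]")
        if self.band_low > self.band_high:
            raise ValueError("band_low must not exceed band_high")
        if self.axial_pitch_mm <= 0:
            raise ValueError("axial pitch must be positive")


#: Default configuration of the volumetric pipeline.
DEFAULT_CONFIG = EstimatorConfig()

#: Configuration for single-specimen measurement mode (in-band end rule).
MEASUREMENT_CONFIG = EstimatorConfig(end_rule="band_40_80")


@dataclass(frozen=True)
class AttenuationEstimate:
    """One attenuation estimate with its provenance.

    ``mu`` is in dB/mm (numerically the scale of the tissue tables);
    it is ``nan`` unless ``status`` is accepted or discarded (discarded
    estimates keep the raw value for inspection but carry no usable mu).
    """

    mu: float
    p_start: float
    p_end: float
    row_start: int
    row_end: int
    L_mm: float
    status: Status

    @property
    def accepted(self) -> bool:
        return self.status is Status.ACCEPTED

    @classmethod
    def no_segment(cls) -> "AttenuationEstimate":
        return cls(math.nan, math.nan, math.nan, -1, -1, math.nan, Status.NO_SEGMENT)


def attenuation_coefficient(p_i: float, p_l: float, n_rows: int,
                            config: EstimatorConfig = DEFAULT_CONFIG) -> AttenuationEstimate:
    """Evaluate the two-point formula and apply the discard rules.

    Parameters
    ----------
    p_i, p_l :
        Gray values at the starting and ending rows; both must be > 0.
    n_rows :
        Number of rows between the starting and ending rows; the segment
        length is ``L = n_rows * axial_pitch_mm``.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    if p_i <= 0 or p_l <= 0:
        raise ValueError("undefined log ratio: gray endpoints must be positive")
    L_mm = n_rows * config.axial_pitch_mm
    mu = 10.0 * math.log10(p_i / p_l) / L_mm
    if mu > config.discard_high:
        status = Status.DISCARDED_HIGH
    elif mu < 0.0:
        status = Status.DISCARDED_NEGATIVE
    else:
        status = Status.ACCEPTED
    return AttenuationEstimate(mu=mu, p_start=float(p_i), p_end=float(p_l),
                               row_start=0, row_end=n_rows, L_mm=L_mm, status=status)


def find_start_row(column: Sequence[float],
                   config: EstimatorConfig = DEFAULT_CONFIG) -> tuple[int, float]:
    """Locate the starting row and gray value of a depth profile.

    Under ``fourth_largest``, ``p_start`` is the fourth value of the
    descending sort and ``row_start`` the earliest row attaining it
    (ties broken toward the probe); under ``max``, the earliest global
    maximum.
    """
    col = np.asarray(column, dtype=float)
    if col.ndim != 1:
        raise ValueError("column must be one-dimensional")
    if config.start_rule == "fourth_largest":
        if col.size < 4:
            raise ValueError("column must have at least 4 pixels")
        p_start = float(np.sort(col)[::-1][3])
    else:
        if col.size < 1:
            raise ValueError("column is empty")
        p_start = float(col.max())
    row_start = int(np.flatnonzero(col == p_start)[0])
    return row_start, p_start


def find_end_row(column: Sequence[float], row_start: int,
                 config: EstimatorConfig = DEFAULT_CONFIG) -> tuple[int, float] | None:
    """Locate the ending row and gray value below ``row_start``.

    Under ``running_mean_lt_45`` the search slides a ``running_window``-
    pixel window starting at ``row_start + 1``; the first window whose
    mean is below ``mean_threshold`` stops the search. ``p_end`` is that
    window mean and the returned row is the window centre. Windows
    truncated by the bottom of the image are not evaluated.

    Under ``band_40_80`` the first single pixel whose gray lies in
    ``[band_low, band_high]`` is the end point.

    Returns ``None`` when no qualifying row exists (no usable segment).
    """
    col = np.asarray(column, dtype=float)
    if not 0 <= row_start < col.size:
        raise ValueError("row_start outside the column")
    if config.end_rule == "running_mean_lt_45":
        w = config.running_window
        if col.size - (row_start + 1) < w:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(col[row_start + 1:], w)
        means = windows.mean(axis=1)
        hits = np.flatnonzero(means < config.mean_threshold)
        if hits.size == 0:
            return None
        first = row_start + 1 + int(hits[0])
        return first + w // 2, float(means[hits[0]])
    else:
        tail = col[row_start + 1:]
        in_band = (tail >= config.band_low) & (tail <= config.band_high)
        hits = np.flatnonzero(in_band)
        if hits.size == 0:
            return None
        r = row_start + 1 + int(hits[0])
        return r, float(col[r])


def estimate_column(column: Sequence[float],
                    config: EstimatorConfig = DEFAULT_CONFIG) -> AttenuationEstimate:
    """Estimate the attenuation coefficient of one A-line.

    Composes :func:`find_start_row`, :func:`find_end_row` and
    :func:`attenuation_coefficient`. Columns whose starting gray value
    does not rise above the end criterion (all-background or blank
    A-lines with no tissue surface) yield ``no_segment``, as do columns
    that never decay below the end criterion (e.g. saturated A-lines).
    """
    col = np.asarray(column, dtype=float)
    min_len = max(4, config.running_window + 4)
    if col.size < min_len:
        raise ValueError(f"column must have at least {min_len} pixels")
    row_start, p_start = find_start_row(col, config)
    floor = (config.mean_threshold if config.end_rule == "running_mean_lt_45"
             else config.band_high)
    if p_start <= floor:
        # no bright surface above the end criterion -> nothing to measure
        return AttenuationEstimate.no_segment()
    end = find_end_row(col, row_start, config)
    if end is None:
        return AttenuationEstimate.no_segment()
    row_end, p_end = end
    if p_end <= 0:
        return AttenuationEstimate.no_segment()
    est = attenuation_coefficient(p_start, p_end, row_end - row_start, config)
    return replace(est, row_start=row_start, row_end=row_end)


@dataclass
class BScanEstimates:
    """Per-column estimates of one B-scan plus a status summary."""

    estimates: list[AttenuationEstimate]
    counts: dict[Status, int] = field(default_factory=dict)

    @property
    def mu(self) -> np.ndarray:
        """Accepted mu per column, nan elsewhere."""
        return np.array([e.mu if e.accepted else math.nan for e in self.estimates])

    @property
    def accepted_fraction(self) -> float:
        n = len(self.estimates)
        return self.counts.get(Status.ACCEPTED, 0) / n if n else math.nan


def estimate_bscan(bscan: np.ndarray,
                   config: EstimatorConfig = DEFAULT_CONFIG) -> BScanEstimates:
    """Estimate the attenuation coefficient of every column of a B-scan."""
    img = np.asarray(bscan)
    if img.ndim != 2:
        raise ValueError("B-scan must be a 2D image")
    ests = [estimate_column(img[:, c], config) for c in range(img.shape[1])]
    counts: dict[Status, int] = {}
    for e in ests:
        counts[e.status] = counts.get(e.status, 0) + 1
    return BScanEstimates(estimates=ests, counts=counts)
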