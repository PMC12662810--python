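"""Scan geometry of the swept-source OCT probe.

A single B-scan covers an 11 mm depth by 5 mm lateral field. Depth is
sampled at a fixed axial pixel pitch of 0.024445 mm/row, so the default
448-row image spans ~10.95 mm. Volumes are acquired as ordered B-scan
stacks with a configurable inter-slice spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Axial pixel pitch of the system, mm per image row.
AXIAL_PITCH_MM = 0.024445

#: Maximum imaging depth of the probe, mm.
MAX_DEPTH_MM = 11.0


@dataclass(frozen=True)
class ScanGeometry:
    """Pixel-to-millimetre mapping for a B-scan stack.

    Parameters
    ----------
    n_rows :
        Axial pixels per A-line (image rows).
    n_cols :
        A-lines per B-scan (image columns).
    axial_pitch_mm :
        Millimetres of depth per image row.
    lateral_pitch_mm :
        Millimetres per image column. Default spreads the 5 mm lateral
        field over 512 columns.
    slice_spacing_mm :
        Distance between consecutive B-scans in a stack.
    """

    n_rows: int = 448
    n_cols: int = 512
    axial_pitch_mm: float = AXIAL_PITCH_MM
    lateral_pitch_mm: float = 5.0 / 512
    slice_spacing_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("image dimensions must be positive")
        if self.axial_pitch_mm <= 0 or self.lateral_pitch_mm <= 0:
            raise ValueError("pixel pitches must be positive")
        if self.slice_spacing_mm <= 0:
            raise ValueError("slice spacing must be positive")
        if self.depth_mm > MAX_DEPTH_MM:
            raise ValueError(
                f"depth {self.depth_mm:.3f} mm exceeds the {MAX_DEPTH_MM} mm probe range"
            )

    @property
    def depth_mm(self) -> float:
        """Total imaged depth, n_rows x axial_pitch_mm."""
        return self.n_rows * self.axial_pitch_mm

    @property
    def width_mm(self) -> float:
        """Total lateral field, n_cols x lateral_pitch_mm."""
        return self.n_cols * self.lateral_pitch_mm

    def row_to_mm(self, row: float) -> float:
        return row * self.axial_pitch_mm

    def mm_to_row(self, depth_mm: float) -> int:
        return int(round(depth_mm / self.axial_pitch_mm))


def axial_resolution_um(center_wavelength_nm: float = 1310.0,
                        bandwidth_nm: float = 100.0) -> float:
    """Theoretical axial resolution of a Gaussian-spectrum OCT source.

    The round-trip coherence length ``(2 ln 2 / pi) * lambda0**2 / dlambda``
    in air. For the system's 1310 nm source with a 100 nm spectral
    bandwidth this evaluates to 7.57 um, i.e. 7.6 um at the printed
    precision.

    Returns the resolution in micrometres.
    """
    if center_wavelength_nm <= 0 or bandwidth_nm <= 0:
        raise ValueError("wavelength and bandwidth must be positive")
    l_c_nm = (2.0 * math.log(2.0) / math.pi) * center_wavelength_nm ** 2 / bandwidth_nm
    return l_c_nm / 1000.0
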