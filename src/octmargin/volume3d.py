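"""Interleaved volume assembly, surface extraction and classified 3D rendering.

Bidirectional raster passes over the same specimen are merged by
*interleaving*: backward passes are flipped to a common spatial order and
the P passes are woven position-major (slice i of pass p lands at output
index ``i*P + p``), dividing the effective slice spacing by P (e.g. ten
passes turn 0.187 mm stacks into 0.0187 mm spacing). The permutation is
recorded and invertible.

Per B-scan, the tissue surface is found by binarizing at gray > 70,
cleaning the mask with morphological opening then closing (3x3 square,
one iteration each), and taking the first foreground row of each column.
Column-wise two-point attenuation estimates form an attenuation volume
whose values are classified into three zones for display:

* red, mu in [0, 5): tumor-probable, brightness ramping up with mu;
* yellow, mu in [5, 6): boundary/transition zone;
* green, mu in [6, 11]: peritumoral brain, brightness ramping up with mu;
* white: undefined or out-of-range values, excluded from rendering.

The top surface is rendered as a vertex-colored height-field mesh that
follows the specimen topography; the four lateral faces are binarized
(> 70) images colored with the same palette.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.morphology import closing as _morph_closing
from skimage.morphology import opening as _morph_opening

from .attenuation import DEFAULT_CONFIG, EstimatorConfig, Status, estimate_bscan
from .phantom import PassRecord

__all__ = [
    "VolumeStack", "AttenuationVolume", "VolumeRender",
    "interleave_passes", "deinterleave", "extract_surface",
    "attenuation_volume", "classify_color", "render_volume",
    "SURFACE_THRESHOLD",
]

#: Binarization threshold for surface extraction and side faces (gray > 70).
SURFACE_THRESHOLD = 70

ZONE_WHITE_RGB = (255, 255, 255)
ZONE_YELLOW_RGB = (255, 255, 0)
RED_RAMP = (96, 255)     # dark red near mu=0, bright red near mu=5
GREEN_RAMP = (96, 255)   # dark green near mu=6, bright green near mu=11


@dataclass
class VolumeStack:
    """An ordered stack of B-scans with spacing and ordering provenance.

    ``provenance`` lists, for each output slice, the ``(pass_index,
    slice_index)`` it came from in the original pass records (with slice
    indices referring to the stored acquisition order).
    """

    slices: np.ndarray             # (n_slices, n_rows, n_cols)
    slice_spacing_mm: float
    positions_mm: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("stack must be (n_slices, n_rows, n_cols)")
        if self.slice_spacing_mm <= 0:
            raise ValueError("slice spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


def interleave_passes(passes: Sequence[PassRecord],
                      base_spacing_mm: float) -> VolumeStack:
    """Weave bidirectional passes into one finely-spaced volume stack.

    Backward passes are reversed to the common forward order first; with
    P passes of N slices each, the output has N*P slices at spacing
    ``base_spacing_mm / P``, ordered position-major then pass-major.
    """
    if not passes:
        raise ValueError("need at least one pass")
    n = len(passes[0].slices)
    if any(len(p.slices) != n for p in passes):
        raise ValueError("ragged pass lengths")
    if base_spacing_mm <= 0:
        raise ValueError("base spacing must be positive")
    P = len(passes)
    out_slices, provenance, positions = [], [], []
    fine = base_spacing_mm / P
    for i in range(n):
        for p_idx, rec in enumerate(passes):
            # stored order of a backward pass is spatially reversed
            j = n - 1 - i if rec.direction == "backward" else i
            out_slices.append(np.asarray(rec.slices[j]))
            provenance.append((p_idx, j))
            positions.append(i * base_spacing_mm + p_idx * fine)
    return VolumeStack(slices=np.stack(out_slices), slice_spacing_mm=fine,
                       positions_mm=np.asarray(positions), provenance=provenance)


def deinterleave(stack: VolumeStack, n_passes: int) -> list[list[np.ndarray]]:
    """Invert :func:`interleave_passes` using the recorded provenance.

    Returns per-pass slice lists in their original stored order.
    """
    n = stack.n_slices // n_passes
    out: list[list] = [[None] * n for _ in range(n_passes)]
    for out_idx, (p_idx, j) in enumerate(stack.provenance):
        out[p_idx][j] = stack.slices[out_idx]
    if any(s is None for sl in out for s in sl):
        raise ValueError("provenance does not cover all slices")
    return out


def extract_surface(bscan: np.ndarray, threshold: int = SURFACE_THRESHOLD,
                    footprint: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-column tissue surface index of one B-scan.

    Binarize at ``gray > threshold``, clean with one opening then one
    closing (3x3 square footprint by default), and return the first
    foreground row per column (nan where a column has none).
    """
    img = np.asarray(bscan)
    if img.ndim != 2:
        raise ValueError("B-scan must be 2D")
    if footprint is None:
        footprint = np.ones((3, 3), dtype=bool)
    # border-replicating opening then closing keeps edge columns intact
    mask = img > threshold
    mask = _morph_opening(mask, footprint)
    mask = _morph_closing(mask, footprint)
    any_fg = mask.any(axis=0)
    first = mask.argmax(axis=0).astype(float)
    first[~any_fg] = math.nan
    return first


def surface_matrix(stack: VolumeStack,
                   threshold: int = SURFACE_THRESHOLD) -> np.ndarray:
    """Surface indices for every (slice, column) of a stack."""
    return np.stack([extract_surface(s, threshold) for s in stack.slices])


@dataclass
class AttenuationVolume:
    """Column-wise attenuation over a stack: (n_slices, n_cols), nan = undefined."""

    mu: np.ndarray
    status_counts: dict = field(default_factory=dict)

    @property
    def defined_fraction(self) -> float:
        return float(np.isfinite(self.mu).mean())


def attenuation_volume(stack: VolumeStack,
                       config: EstimatorConfig = DEFAULT_CONFIG) -> AttenuationVolume:
    """Two-point attenuation estimate for every A-line of a stack.

    Discarded and segment-less columns are undefined (nan); defined
    values lie in [0, 11] by the discard rules.
    """
    rows = []
    counts: dict[Status, int] = {}
    for s in stack.slices:
        res = estimate_bscan(s, config)
        rows.append(res.mu)
        for k, v in res.counts.items():
            counts[k] = counts.get(k, 0) + v
    return AttenuationVolume(mu=np.stack(rows), status_counts=counts)


def classify_color(mu: float) -> tuple[str, tuple[int, int, int]]:
    """Map an attenuation value to its display zone and RGB color.

    Zones: red for mu in [0,5) (tumor-probable, darker near 0), yellow
    for [5,6) (boundary), green for [6,11] (peritumoral, darker near 6);
    anything undefined or outside [0,11] is white and excluded.
    """
    if mu is None or not np.isfinite(mu) or mu < 0 or mu > 11:
        return "white", ZONE_WHITE_RGB
    if mu < 5.0:
        lo, hi = RED_RAMP
        level = int(round(lo + (hi - lo) * (mu / 5.0)))
        return "red", (level, 0, 0)
    if mu < 6.0:
        return "yellow", ZONE_YELLOW_RGB
    lo, hi = GREEN_RAMP
    level = int(round(lo + (hi - lo) * ((mu - 6.0) / 5.0)))
    return "green", (0, level, 0)


def classify_volume(att: AttenuationVolume) -> np.ndarray:
    """RGB classification image of an attenuation matrix, shape (..., 3)."""
    flat = att.mu.ravel()
    out = np.empty((flat.size, 3), dtype=np.uint8)
    for i, m in enumerate(flat):
        out[i] = classify_color(m)[1]
    return out.reshape(att.mu.shape + (3,))


@dataclass
class VolumeRender:
    """Rendered 3D reconstruction: surface mesh + four colored side faces."""

    vertices: np.ndarray           # (n_vertices, 3) in mm: (y=slice, x=col, z=depth)
    faces: np.ndarray              # (n_faces, 3) vertex indices
    vertex_colors: np.ndarray      # (n_vertices, 3) uint8
    side_faces: dict               # name -> RGB image (uint8)
    surface: np.ndarray            # surface index matrix (n_slices, n_cols)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces,
                               vertex_colors=self.vertex_colors, process=False)


def _side_face_rgb(gray_face: np.ndarray, surface_idx: np.ndarray,
                   mu_line: np.ndarray, threshold: int) -> np.ndarray:
    """Color one lateral face: binarize > threshold, blank above-surface
    voxels, color supra-threshold voxels by the local column attenuation."""
    n_rows, n_lat = gray_face.shape
    rgb = np.full((n_rows, n_lat, 3), 255, dtype=np.uint8)
    mask = gray_face > threshold
    rows = np.arange(n_rows)[:, None]
    surf = np.where(np.isfinite(surface_idx), surface_idx, n_rows)[None, :]
    mask &= rows >= surf           # upper voxels outside the surface blanked
    for j in range(n_lat):
        zone_rgb = classify_color(mu_line[j])[1]
        rgb[mask[:, j], j] = zone_rgb
    return rgb


def render_volume(att: AttenuationVolume, surface: np.ndarray, stack: VolumeStack,
                  lateral_pitch_mm: float, axial_pitch_mm: float,
                  threshold: int = SURFACE_THRESHOLD) -> VolumeRender:
    """Build the classified 3D reconstruction of a volume stack.

    The top surface becomes a height-field mesh over the (slice, column)
    grid at the extracted surface depths, vertex-colored by the zone of
    the local attenuation estimate; quads with any undefined corner are
    skipped. Four lateral faces are colored per :func:`_side_face_rgb`.
    """
    n_slices, n_cols = surface.shape
    if att.mu.shape != surface.shape:
        raise ValueError("attenuation and surface matrices must align")
    if not np.isfinite(surface).any():
        raise ValueError("no tissue detected")

    idx = -np.ones((n_slices, n_cols), dtype=int)
    verts, colors = [], []
    for i in range(n_slices):
        for j in range(n_cols):
            if np.isfinite(surface[i, j]):
                idx[i, j] = len(verts)
                verts.append((i * stack.slice_spacing_mm, j * lateral_pitch_mm,
                              surface[i, j] * axial_pitch_mm))
                colors.append(classify_color(att.mu[i, j])[1])
    faces = []
    for i in range(n_slices - 1):
        for j in range(n_cols - 1):
            a, b = idx[i, j], idx[i, j + 1]
            c, d = idx[i + 1, j], idx[i + 1, j + 1]
            if min(a, b, c, d) >= 0:
                faces.append((a, b, d))
                faces.append((a, d, c))
    sides = {
        "front": _side_face_rgb(stack.slices[0], surface[0], att.mu[0], threshold),
        "back": _side_face_rgb(stack.slices[-1], surface[-1], att.mu[-1], threshold),
        "left": _side_face_rgb(stack.slices[:, :, 0].T, surface[:, 0],
                               att.mu[:, 0], threshold),
        "right": _side_face_rgb(stack.slices[:, :, -1].T, surface[:, -1],
                                att.mu[:, -1], threshold),
    }
    return VolumeRender(
        vertices=np.asarray(verts, dtype=float),
        faces=np.asarray(faces, dtype=int) if faces else np.empty((0, 3), int),
        vertex_colors=np.asarray(colors, dtype=np.uint8),
        side_faces=sides,
        surface=surface,
    )
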