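"""Synthetic OCT phantom: A-lines, B-scans, boundary scenes and multi-pass volumes.

The generator is the statistical inverse of the two-point attenuation
estimator: below a bright tissue surface located at a probe standoff of a
few millimetres, the noise-free gray value decays as

    I(z) = surface_intensity * 10**(-mu_true * z / 10)

for depth-below-surface ``z`` in mm, so the estimator recovers ``mu_true``
(dB/mm) up to quantization. Speckle is modelled as a multiplicative,
mean-one gamma field, spatially smoothed to the system's effective
resolution cell; a small additive Gaussian term models detector/background
noise. Gray values are clipped to [0, 255] and quantized to 8 bits.

Tissue presets carry the measured ex vivo statistics of each tissue class
(attenuation mean +/- SD across specimens; probe standoff distribution),
so seeded cohorts of synthetic specimens reproduce the published group
statistics. Attenuation varies at the specimen level: one draw per
specimen, shared by all A-lines of that specimen.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.stats import truncnorm

from .geometry import ScanGeometry

__all__ = [
    "TissuePreset",
    "Region",
    "Inclusion",
    "SceneSpec",
    "GroundTruth",
    "PassRecord",
    "PRESETS",
    "synth_aline",
    "synth_bscan",
    "synth_pass_stacks",
    "synth_specimen_aline",
]

SeedLike = Union[int, np.random.SeedSequence, None]

#: Attenuation values outside (0, 11) dB/mm are not estimable by the
#: two-point rule (the discard rules reject them); presets must stay inside.
MU_MAX = 11.0

#: Speckle-grain smoothing of the multiplicative noise field, in pixels.
#: The gamma shape parameter of the presets together with this correlation
#: scale sets the effective speckle contrast of the rendered gray images
#: (see docs/methods.md for the calibration rationale).
SPECKLE_AXIAL_SIGMA = 2.0
SPECKLE_LATERAL_SIGMA = 1.0

#: SD of the additive Gaussian background noise, gray levels.
BACKGROUND_NOISE_SD = 2.0


@dataclass(frozen=True)
class TissuePreset:
    """Generative parameters of one tissue class.

    ``mu_mean`` / ``mu_sd`` are the across-specimen attenuation statistics
    (dB/mm, numerically the published mm^-1 scale); the standoff fields
    describe the probe-to-tissue distance as a truncated normal.
    """

    name: str
    mu_mean: float
    mu_sd: float
    surface_intensity: float = 200.0
    standoff_mean_mm: float = 2.22
    standoff_sd_mm: float = 0.89
    standoff_min_mm: float = 0.4
    standoff_max_mm: float = 4.6
    speckle_shape: float = 100.0
    background_level: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.mu_mean < MU_MAX:
            raise ValueError("mu_mean must lie in (0, 11)")
        if self.mu_sd < 0:
            raise ValueError("mu_sd must be >= 0")
        if not 0 <= self.surface_intensity <= 255:
            raise ValueError("surface_intensity must lie in [0, 255]")
        if not (self.standoff_min_mm <= self.standoff_mean_mm <= self.standoff_max_mm):
            raise ValueError("standoff mean must lie within [min, max]")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")

    def draw_mu(self, rng: np.random.Generator, size=None):
        """Specimen-level attenuation draw, normal truncated to (0, 11)."""
        if self.mu_sd == 0:
            return (np.full(size, self.mu_mean) if size is not None
                    else self.mu_mean)
        a = (0.0 - self.mu_mean) / self.mu_sd
        b = (MU_MAX - self.mu_mean) / self.mu_sd
        out = truncnorm.rvs(a, b, loc=self.mu_mean, scale=self.mu_sd,
                            size=size, random_state=rng)
        return float(out) if size is None else out

    def draw_standoff(self, rng: np.random.Generator, size=None):
        """Probe-to-surface distance draw, truncated normal, mm."""
        a = (self.standoff_min_mm - self.standoff_mean_mm) / self.standoff_sd_mm
        b = (self.standoff_max_mm - self.standoff_mean_mm) / self.standoff_sd_mm
        out = truncnorm.rvs(a, b, loc=self.standoff_mean_mm,
                            scale=self.standoff_sd_mm, size=size, random_state=rng)
        return float(out) if size is None else out


def _glioma_tumor(name: str, mu_mean: float, mu_sd: float) -> TissuePreset:
    # supratentorial glioma scans: standoff 2.22 +/- 0.89 mm, range 0.4-4.6
    return TissuePreset(name, mu_mean, mu_sd, surface_intensity=124.0)


def _peritumoral(name: str, mu_mean: float, mu_sd: float) -> TissuePreset:
    # peritumoral scans: standoff 2.08 +/- 0.86 mm, range 0.7-4.0; brighter
    # surface peak than tumor tissue (~140 vs ~110 on the trend profile)
    return TissuePreset(name, mu_mean, mu_sd, surface_intensity=164.0,
                        standoff_mean_mm=2.08, standoff_sd_mm=0.86,
                        standoff_min_mm=0.7, standoff_max_mm=4.0)


#: Shipped tissue presets, keyed by short name. Attenuation means/SDs are
#: the published ex vivo group statistics per tissue class.
PRESETS: dict[str, TissuePreset] = {
    p.name: p
    for p in (
        _glioma_tumor("grade4_tumor", 4.62, 0.98),
        _glioma_tumor("grade3_tumor", 4.50, 1.47),
        _glioma_tumor("grade2_tumor", 5.28, 1.96),
        _glioma_tumor("hgg_tumor", 4.56, 1.23),
        _glioma_tumor("all_glioma", 4.81, 1.51),
        _peritumoral("peritumoral_all", 6.40, 0.53),
        _peritumoral("peritumoral_hgg", 6.41, 0.58),
        _peritumoral("cerebellum_normal", 4.17, 0.44),
        _glioma_tumor("metastasis_cerebellar", 5.14, 0.68),
    )
}


@dataclass(frozen=True)
class Region:
    """A lateral column range [col_start, col_stop) filled with one tissue.

    ``mu`` pins the attenuation of the region; when ``None`` it is drawn
    from the preset at generation time (specimen-level draw).
    """

    col_start: int
    col_stop: int
    preset: TissuePreset
    mu: Optional[float] = None


@dataclass(frozen=True)
class Inclusion:
    """A thin bright layer below the surface (nerve/epineurium-like).

    Such structures are detectable at depths < 3 mm, hence the depth cap.
    """

    depth_mm: float
    thickness_mm: float
    gain: float

    def __post_init__(self) -> None:
        if not 0 < self.depth_mm < 3.0:
            raise ValueError("inclusion depth must lie in (0, 3) mm")
        if self.thickness_mm <= 0 or self.gain <= 0:
            raise ValueError("inclusion thickness and gain must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full specification of one synthetic B-scan (or volume) scene."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    regions: tuple = ()
    inclusion: Optional[Inclusion] = None
    surface_roughness_mm: float = 0.05
    surface_correlation_mm: float = 0.5
    seed: SeedLike = 0
    noise: bool = True
    standoff_mm: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("scene must have at least one region")
        regs = sorted(self.regions, key=lambda r: r.col_start)
        if regs[0].col_start != 0 or regs[-1].col_stop != self.geometry.n_cols:
            raise ValueError("regions must partition [0, n_cols)")
        for a, b in zip(regs, regs[1:]):
            if a.col_stop != b.col_start:
                raise ValueError("regions must partition [0, n_cols)")
        if self.surface_roughness_mm < 0:
            raise ValueError("surface roughness must be >= 0")


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic B-scan."""

    mu_true: np.ndarray          # per-column attenuation, dB/mm
    surface_row: np.ndarray      # per-column surface row index
    standoff_mm: float           # drawn probe-to-tissue distance (mean surface)
    surface_height_mm: np.ndarray  # per-column deviation from the standoff
    seed: object = None

    def to_jsonable(self) -> dict:
        return {
            "mu_true": [float(v) for v in self.mu_true],
            "surface_row": [int(v) for v in self.surface_row],
            "standoff_mm": float(self.standoff_mm),
            "surface_height_mm": [float(v) for v in self.surface_height_mm],
            "seed": repr(self.seed),
        }


def _validate_mu(mu_true: float) -> None:
    if not 0.0 <= mu_true < MU_MAX:
        raise ValueError("preset out of estimable range: mu_true must lie in [0, 11)")


def _speckle_field(rng: np.random.Generator, shape: tuple, gamma_shape: float,
                   sigmas) -> np.ndarray:
    field_ = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=shape)
    if np.ndim(field_) == 1:
        return gaussian_filter1d(field_, sigmas[0], mode="reflect")
    return gaussian_filter(field_, sigmas, mode="reflect")


def _quantize(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def synth_aline(preset: TissuePreset, geometry: ScanGeometry, mu_true: float,
                standoff_mm: float, seed: SeedLike = 0,
                noise_enabled: bool = True) -> np.ndarray:
    """Generate one synthetic A-line (gray column of length ``n_rows``).

    Rows above the surface sit at the preset's background level; the
    surface row has gray ``surface_intensity``; below it the noise-free
    gray follows the exponential decay law at ``mu_true`` dB/mm. Noise
    (speckle + background) is applied when ``noise_enabled``.
    """
    _validate_mu(mu_true)
    if standoff_mm < 0:
        raise ValueError("standoff must be >= 0")
    surface_row = geometry.mm_to_row(standoff_mm)
    if surface_row >= geometry.n_rows:
        raise ValueError("surface out of frame")
    rows = np.arange(geometry.n_rows)
    z_mm = (rows - surface_row) * geometry.axial_pitch_mm
    tissue = rows >= surface_row
    ideal = np.where(
        tissue,
        preset.surface_intensity * 10.0 ** (-mu_true * np.maximum(z_mm, 0.0) / 10.0),
        preset.background_level,
    )
    if not noise_enabled:
        return _quantize(ideal)
    rng = np.random.default_rng(seed)
    speckle = _speckle_field(rng, (geometry.n_rows,), preset.speckle_shape,
                             (SPECKLE_AXIAL_SIGMA,))
    noisy = np.where(tissue, ideal * speckle, ideal)
    noisy = noisy + rng.normal(0.0, BACKGROUND_NOISE_SD, size=noisy.shape)
    return _quantize(noisy)


def synth_bscan(scene: SceneSpec,
                noise_seed: SeedLike = None) -> tuple[np.ndarray, GroundTruth]:
    """Generate one synthetic B-scan and its ground truth.

    All columns share one drawn standoff plus a smooth random surface
    height field (Gaussian-smoothed white noise, correlation length
    ``surface_correlation_mm``); each region contributes its own
    specimen-level attenuation draw. Deterministic under a fixed seed.

    ``noise_seed`` decouples the noise realization from the scene truth:
    two calls with the same scene seed but different noise seeds image
    the same specimen twice (repeat passes differ only minutely).
    """
    geom = scene.geometry
    rng = np.random.default_rng(scene.seed)
    rng_noise = np.random.default_rng(noise_seed) if noise_seed is not None else rng

    regions = sorted(scene.regions, key=lambda r: r.col_start)
    standoff = (scene.standoff_mm if scene.standoff_mm is not None
                else regions[0].preset.draw_standoff(rng))

    # smooth surface topography shared by all columns
    heights = np.zeros(geom.n_cols)
    if scene.surface_roughness_mm > 0:
        white = rng.normal(0.0, 1.0, geom.n_cols)
        sigma_cols = scene.surface_correlation_mm / geom.lateral_pitch_mm
        smooth = gaussian_filter1d(white, sigma_cols, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            heights = smooth / sd * scene.surface_roughness_mm
            heights -= heights.mean()

    mu_col = np.empty(geom.n_cols)
    surf_int = np.empty(geom.n_cols)
    bg = np.empty(geom.n_cols)
    shape_k = np.empty(geom.n_cols)
    for reg in regions:
        mu = reg.mu if reg.mu is not None else reg.preset.draw_mu(rng)
        _validate_mu(mu)
        sl = slice(reg.col_start, reg.col_stop)
        mu_col[sl] = mu
        surf_int[sl] = reg.preset.surface_intensity
        bg[sl] = reg.preset.background_level
        shape_k[sl] = reg.preset.speckle_shape

    surface_row = np.array([geom.mm_to_row(standoff + h) for h in heights])
    surface_row = np.maximum(surface_row, 0)
    if np.any(surface_row >= geom.n_rows):
        raise ValueError("surface out of frame")

    rows = np.arange(geom.n_rows)[:, None]
    z_mm = (rows - surface_row[None, :]) * geom.axial_pitch_mm
    tissue = rows >= surface_row[None, :]
    ideal = np.where(
        tissue,
        surf_int[None, :] * 10.0 ** (-mu_col[None, :] * np.maximum(z_mm, 0.0) / 10.0),
        bg[None, :],
    )
    if scene.inclusion is not None:
        inc = scene.inclusion
        z_lo, z_hi = inc.depth_mm, inc.depth_mm + inc.thickness_mm
        in_layer = tissue & (z_mm >= z_lo) & (z_mm < z_hi)
        ideal = np.where(in_layer, ideal * inc.gain, ideal)

    truth = GroundTruth(mu_true=mu_col, surface_row=surface_row,
                        standoff_mm=float(standoff), surface_height_mm=heights,
                        seed=scene.seed)
    if not scene.noise:
        return _quantize(ideal), truth

    # one gamma shape per image (region-wise shapes rarely differ; use the
    # column-wise field so mixed scenes stay correct)
    speckle = _speckle_field(rng_noise, ideal.shape, float(shape_k.min()),
                             (SPECKLE_AXIAL_SIGMA, SPECKLE_LATERAL_SIGMA))
    noisy = np.where(tissue, ideal * speckle, ideal)
    noisy = noisy + rng_noise.normal(0.0, BACKGROUND_NOISE_SD, size=noisy.shape)
    return _quantize(noisy), truth


@dataclass
class PassRecord:
    """One raster pass over the specimen.

    Backward passes store slices in reversed spatial order (as the
    instrument acquires them) while ``positions_mm`` keeps the true
    position label of each stored slice.
    """

    index: int
    direction: str                      # "forward" | "backward"
    slices: list
    positions_mm: list
    truths: list


def synth_pass_stacks(scene: SceneSpec, n_passes: int,
                      slices_per_pass: int) -> list[PassRecord]:
    """Simulate a bidirectional raster acquisition of one specimen.

    Every pass images the same ``slices_per_pass`` positions spaced by
    the geometry's slice spacing; odd-indexed passes run backward. The
    specimen truth at each position is shared across passes, while each
    pass has its own noise realization, so repeated slices of the same
    position differ only minutely.
    """
    if n_passes < 1 or slices_per_pass < 1:
        raise ValueError("n_passes and slices_per_pass must be >= 1")
    ss = (scene.seed if isinstance(scene.seed, np.random.SeedSequence)
          else np.random.SeedSequence(scene.seed))
    pos_seeds = ss.spawn(slices_per_pass)
    noise_seeds = ss.spawn(n_passes * slices_per_pass)
    spacing = scene.geometry.slice_spacing_mm
    passes: list[PassRecord] = []
    for p in range(n_passes):
        order = range(slices_per_pass)
        direction = "forward"
        if p % 2 == 1:
            order = reversed(range(slices_per_pass))
            direction = "backward"
        slices, positions, truths = [], [], []
        for j in order:
            scene_j = dataclasses.replace(scene, seed=pos_seeds[j])
            img, truth = synth_bscan(scene_j,
                                     noise_seed=noise_seeds[p * slices_per_pass + j])
            slices.append(img)
            positions.append(j * spacing)
            truths.append(truth)
        passes.append(PassRecord(index=p, direction=direction, slices=slices,
                                 positions_mm=positions, truths=truths))
    return passes


def synth_specimen_aline(preset: TissuePreset, geometry: ScanGeometry,
                         rng: np.random.Generator,
                         noise_enabled: bool = True) -> tuple[np.ndarray, float, float]:
    """Draw one synthetic specimen and image its central A-line.

    Draws specimen-level attenuation and standoff from the preset, then
    renders a single A-line. Returns ``(column, mu_true, standoff_mm)``.
    """
    mu = preset.draw_mu(rng)
    standoff = preset.draw_standoff(rng)
    col = synth_aline(preset, geometry, mu, standoff,
                      seed=rng.integers(2**31), noise_enabled=noise_enabled)
    return col, float(mu), float(standoff)
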