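"""Reading and writing of B-scans, stacks, estimate tables and meshes.

B-scans are 8-bit grayscale TIFF or PNG; stacks are multi-page TIFF (one
page per slice) or numbered PNG directories. Ground truth and provenance
travel as JSON sidecars; per-column estimates as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .attenuation import AttenuationEstimate


def read_gray(path) -> np.ndarray:
    """Read a single 8-bit grayscale image (TIFF/PNG)."""
    path = Path(path)
    img = (tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff")
           else iio.imread(path))
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] in (3, 4):   # collapse RGB(A)
        img = img[..., :3].mean(axis=-1)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def write_gray(path, image: np.ndarray) -> None:
    path = Path(path)
    img = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        photometric = "rgb" if img.ndim == 3 else "minisblack"
        tifffile.imwrite(path, img, photometric=photometric)
    else:
        iio.imwrite(path, img)


def read_stack(path) -> np.ndarray:
    """Read an ordered slice stack: multi-page TIFF or a PNG directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no images found in {path}")
        return np.stack([read_gray(f) for f in files])
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def write_stack(path, slices: Sequence[np.ndarray]) -> None:
    """Write a slice stack as multi-page TIFF (or numbered PNGs if a dir)."""
    path = Path(path)
    arr = np.stack([np.asarray(s, dtype=np.uint8) for s in slices])
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(arr):
            iio.imwrite(path / f"slice_{i:04d}.png", s)


def write_attenuation_volume(path, mu: np.ndarray) -> None:
    """Attenuation matrix as 32-bit float TIFF, nan = undefined."""
    tifffile.imwrite(Path(path), np.asarray(mu, dtype=np.float32))


def estimates_to_frame(estimates: Sequence[AttenuationEstimate],
                       slice_index: int = 0) -> pd.DataFrame:
    """Tabulate per-column estimates (slice, column, mu, status, rows, grays)."""
    return pd.DataFrame({
        "slice": slice_index,
        "column": np.arange(len(estimates)),
        "mu": [e.mu for e in estimates],
        "status": [e.status.value for e in estimates],
        "row_start": [e.row_start for e in estimates],
        "row_end": [e.row_end for e in estimates],
        "p_start": [e.p_start for e in estimates],
        "p_end": [e.p_end for e in estimates],
    })


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_mesh_ply(path, render) -> None:
    """Export a vertex-colored surface mesh as PLY."""
    render.to_trimesh().export(Path(path))
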