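"""File I/O: images, float arrays, masks, configs, diagnostics tables."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .ct_model import Geometry, Sinogram

__all__ = [
    "save_float_array",
    "load_float_array",
    "save_image",
    "load_image",
    "save_mask",
    "load_mask",
    "save_sinogram_csv",
    "RunConfig",
    "save_config",
    "load_config",
    "save_json",
    "save_diagnostics_csv",
]


def save_float_array(path: str | Path, arr: np.ndarray) -> None:
    """Lossless portable float container (.npy)."""
    np.save(str(path), np.asarray(arr, dtype=float))


def load_float_array(path: str | Path) -> np.ndarray:
    return np.load(str(path))


def save_image(path: str | Path, image: np.ndarray) -> None:
    """16-bit grayscale TIFF/PNG; values are min-max scaled to the full range."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    scale = (hi - lo) if hi > lo else 1.0
    q = np.round((image - lo) / scale * 65535).astype(np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), q)
    else:
        iio.imwrite(str(path), q)


def load_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as floats in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        return np.load(str(path))
    arr = np.asarray(iio.imread(str(path)), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., 0]
    peak = arr.max()
    return arr / peak if peak > 0 else arr


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 0 else 0)


def save_sinogram_csv(path: str | Path, sino: Sinogram) -> None:
    np.savetxt(str(path), sino.values, delimiter=",")


@dataclass
class RunConfig:
    """Self-describing configuration of one scenario/test run."""

    seed: int = 0
    side: int = 128
    n_angles: int = 50
    n_detectors: int = 128
    sigma: float = 0.175
    truth: str = "STRUCTURE_PRESENT"
    alpha: float = 0.01
    delta: float = 1e-3
    psi: str = "tv"
    quantile: float = 0.99
    dilation_width: int = 3
    max_iters: int = 20000
    tol_primal: float = 1e-5
    tol_feas: float = 1e-4


def save_config(path: str | Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = RunConfig(**data)
    if not 0 < cfg.alpha < 1 or not 0 <= cfg.delta < 1:
        raise ValueError("alpha must be in (0,1) and delta in [0,1)")
    if cfg.psi not in ("tv", "wavelet"):
        raise ValueError(f"unknown psi kind {cfg.psi!r}")
    return cfg


def save_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)


def save_diagnostics_csv(path: str | Path, rows: list[dict]) -> None:
    if not rows:
        Path(path).write_text("")
        return
    keys = sorted({k for row in rows for k in row})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
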