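"""Configuration and image I/O for the holography pipeline.

Configs are YAML with units embedded in field names (wavelength_nm, z2_mm,
pixel_um) so unit bugs surface at the boundary; everything is converted to
SI on load.  Quantitative images travel as 32-bit float TIFF; previews and
quantized recordings as 8/16-bit grayscale PNG.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .propagation import OpticalGeometry
from .recovery import RecoveryConfig
from .counting import CountingConfig

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_image",
    "write_float_tiff",
    "write_png",
    "write_preview_png",
    "write_manifest",
]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


_GEOMETRY_DEFAULTS = {
    "wavelength_nm": 587.0,
    "z2_mm": 0.5,
    "z1_cm": 5.0,
    "pixel_um": 1.12,
    "rows": 512,
    "cols": 512,
}


@dataclass
class RunConfig:
    """One run's full parameter set; round-trips losslessly through YAML."""

    geometry: dict = field(default_factory=lambda: dict(_GEOMETRY_DEFAULTS))
    recovery: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=lambda: {"contrast_threshold": 0.1})
    counting: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        geo = dict(_GEOMETRY_DEFAULTS)
        geo.update(self.geometry or {})
        self.geometry = geo
        for key in ("wavelength_nm", "z2_mm", "z1_cm", "pixel_um"):
            if not (float(geo[key]) > 0):
                raise ConfigError(f"geometry.{key} must be positive, got {geo[key]}")
        for key in ("rows", "cols"):
            if int(geo[key]) < 2:
                raise ConfigError(f"geometry.{key} must be >= 2, got {geo[key]}")

    def optical_geometry(self) -> OpticalGeometry:
        g = self.geometry
        return OpticalGeometry(
            wavelength=float(g["wavelength_nm"]) * 1e-9,
            z2=float(g["z2_mm"]) * 1e-3,
            z1=float(g["z1_cm"]) * 1e-2,
            pixel_pitch=float(g["pixel_um"]) * 1e-6,
            grid_rows=int(g["rows"]),
            grid_cols=int(g["cols"]),
        )

    def recovery_config(self) -> RecoveryConfig:
        try:
            return RecoveryConfig(**self.recovery)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid recovery block: {exc}") from exc

    def counting_config(self) -> CountingConfig:
        try:
            kwargs = dict(self.counting)
            if "class_thresholds" in kwargs and kwargs["class_thresholds"] is not None:
                kwargs["class_thresholds"] = tuple(kwargs["class_thresholds"])
            return CountingConfig(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid counting block: {exc}") from exc

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; None gives the documented defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {"geometry", "recovery", "metrics", "counting", "seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Images


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float64.

    Integer PNGs are rescaled to [0, 1] by their dtype's full range; float
    TIFFs pass through unchanged.  RGB inputs are rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def write_float_tiff(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_png(path: str | Path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a non-negative image to PNG, scaled to the full integer range."""
    image = np.asarray(image, dtype=np.float64)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    peak = float(image.max())
    scale = (2**bit_depth - 1) / peak if peak > 0 else 1.0
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(str(path), np.round(image * scale).astype(dtype))


def write_preview_png(path: str | Path, image: np.ndarray) -> None:
    """8-bit preview with min-max stretch (display only, not quantitative)."""
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    stretched = (image - lo) / (hi - lo) if hi > lo else np.zeros_like(image)
    iio.imwrite(str(path), np.round(stretched * 255).astype(np.uint8))


def write_manifest(
    path: str | Path, config: RunConfig, outputs: list[str | Path]
) -> dict:
    """Write a reproducibility manifest: config echo, seed, output hashes."""
    from . import __version__

    entries = {}
    for out in outputs:
        out = Path(out)
        entries[out.name] = hashlib.sha256(out.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
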