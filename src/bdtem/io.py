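"""Tile and manifest I/O, configuration loading, reproducibility stamps.

Tiles are single-channel 8- or 16-bit grayscale TIFFs; 8-bit input is
widened to 16 bits (x257) with a warning.  Manifests and solutions are
JSON; configuration is TOML validated against a closed key set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import tifffile

from . import __version__

__all__ = [
    "FormatError",
    "Config",
    "read_tile",
    "write_tile",
    "load_config",
    "write_json",
    "read_json",
    "provenance",
]

log = logging.getLogger("bdtem")


class FormatError(ValueError):
    """Unsupported raster layout (RGB, multi-page, float TIFF, ...)."""


def read_tile(path) -> np.ndarray:
    """Read a single-channel grayscale TIFF tile as uint16.

    8-bit input is accepted and widened (x257) with a warning; RGB or
    multi-page input raises :class:`FormatError`.
    """
    with tifffile.TiffFile(str(path)) as tf:
        if len(tf.pages) != 1:
            raise FormatError(f"{path}: multi-page TIFF not supported")
        arr = tf.pages[0].asarray()
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        return arr
    if arr.dtype == np.uint8:
        log.warning("%s: widening 8-bit tile to 16 bits", path)
        return arr.astype(np.uint16) * 257
    raise FormatError(f"{path}: unsupported dtype {arr.dtype}")


def write_tile(path, raster: np.ndarray) -> None:
    """Write a uint8/uint16 grayscale raster as a single-page TIFF."""
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise FormatError(f"cannot write shape {arr.shape} as a grayscale tile")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.uint16) * 257
    if arr.dtype != np.uint16:
        raise FormatError(f"unsupported dtype {arr.dtype}; pass uint8 or uint16")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def tile_name(section: int, st_row: int, st_col: int, i: int, j: int) -> str:
    """Canonical tile file name: s{section}_r{row}c{col}_t{i}{j}.tif."""
    return f"s{section}_r{st_row}c{st_col}_t{i}{j}.tif"


@dataclass(frozen=True)
class Config:
    """Tool defaults; every key optional in the TOML, unknown keys rejected."""

    tile_px: int = 6000
    grid_rows: int = 3
    grid_cols: int = 3
    intra_overlap_frac: float = 0.15
    inter_overlap_px: int = 600
    pixel_size_nm: float = 3.0
    exposure_ms: float = 120.0
    stage_move_ms: float = 37.0
    stage_settle_ms: float = 10.0
    cricket_settle_ms: float = 6.0
    transition_min: float = 2.2
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> Config:
    """Load a TOML config; unknown keys are rejected with ValueError."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f.name for f in fields(Config)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**data)


def provenance(seed: int | None = None, config: Config | None = None) -> dict:
    """Reproducibility stamp embedded in every JSON artifact."""
    return {
        "tool": "bdtem",
        "version": __version__,
        "seed": seed,
        "config_hash": config.config_hash() if config else None,
    }


def write_json(path, payload: dict, seed: int | None = None, config: Config | None = None) -> None:
    payload = dict(payload)
    payload["_provenance"] = provenance(seed=seed, config=config)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
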