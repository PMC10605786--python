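"""File I/O and run manifests: CSV myograph traces, TOML configs, TIFF
stacks, and checksummed output manifests."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fibergap import FiberImage, LayerAnnotation
from .mechanics import RingGeometry
from .qbrm import PolarizationStack

MYOGRAPH_COLUMNS = ["pressure_mmHg", "outer_diameter_um", "axial_force_mN"]


class IOError_(ValueError):
    pass


def read_myograph_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MYOGRAPH_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"myograph CSV missing columns {missing}")
    return df


def read_geometry_toml(path) -> tuple[RingGeometry, float]:
    """Geometry config: outer/inner perimeters (um), unloaded and stretched
    lengths (mm).  Returns (geometry, stretched_length_mm)."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    geom = RingGeometry(
        outer_perimeter_um=cfg["outer_perimeter_um"],
        inner_perimeter_um=cfg["inner_perimeter_um"],
        unloaded_length_mm=cfg["unloaded_length_mm"],
    )
    return geom, float(cfg["stretched_length_mm"])


def read_fiber_config(path) -> dict:
    """ROI/annotation config for fiber-gap analysis."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    cfg["annotation"] = LayerAnnotation(
        intima=tuple(cfg["intima_cols"]),
        media=tuple(cfg["media_cols"]),
        adventitia=tuple(cfg["adventitia_cols"]),
    )
    cfg["roi"] = tuple(cfg["roi"])
    return cfg


def read_fiber_tiff(path, pixel_size_um: float, annotation: LayerAnnotation | None = None) -> FiberImage:
    raster = tifffile.imread(path)
    if raster.ndim != 2:
        raise IOError_(f"expected single-channel 2-D TIFF, got shape {raster.shape}")
    return FiberImage(raster=np.asarray(raster, dtype=float), pixel_size_um=pixel_size_um, annotation=annotation)


def read_polarization_tiff(path, pixel_size_um: float = 1.0) -> PolarizationStack:
    """Six-page multi-page TIFF, page k at polarizer angle k*30 deg."""
    frames = tifffile.imread(path)
    if frames.ndim != 3 or frames.shape[0] != 6:
        raise IOError_(f"expected a 6-page stack, got shape {frames.shape}")
    return PolarizationStack(frames=np.asarray(frames, dtype=float), pixel_size_um=pixel_size_um)


def write_polarization_tiff(path, stack: PolarizationStack) -> None:
    tifffile.imwrite(path, stack.frames.astype(np.float32))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, inputs: dict, seed: int | None = None) -> Path:
    """Checksummed machine-readable manifest next to a stage's outputs."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "seed": seed,
        "outputs": {p.name: _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
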