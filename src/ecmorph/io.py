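"""File I/O: TIFF height maps with JSON sidecars, TSV force curves, images.

Formats
-------
* Height maps: 32-bit float TIFF (values in nm) + ``<stem>.json`` sidecar
  holding ``pixel_size_um``, ``units`` and any extra metadata.
* Force curves: TSV with header ``segment\tposition_nm\tforce_pN`` and
  ``segment`` in {approach, retract}.
* Fluorescence / spot images: 8- or 16-bit grayscale TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .containers import ForceCurve, HeightMap

__all__ = [
    "write_height_map",
    "read_height_map",
    "write_force_curve",
    "read_force_curve",
    "write_image",
    "read_image",
]

CURVE_COLUMNS = ["segment", "position_nm", "force_pN"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_height_map(hmap: HeightMap, path: str | Path) -> Path:
    """Write a height map as float32 TIFF (nm) plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, hmap.heights.astype(np.float32))
    meta = {"pixel_size_um": hmap.pixel_size_um, "units": "nm", **hmap.meta}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_height_map(path: str | Path, meta_path: str | Path | None = None) -> HeightMap:
    """Read a height map TIFF and its JSON sidecar (``pixel_size_um`` required)."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta: dict[str, Any] = json.loads(meta_path.read_text())
    try:
        pixel_size = float(meta.pop("pixel_size_um"))
    except KeyError:
        raise KeyError(f"'pixel_size_um' missing from {meta_path}") from None
    heights = np.asarray(tifffile.imread(path), dtype=float)
    return HeightMap(heights, pixel_size, meta)


def write_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for name in ("approach", "retract"):
        seg = curve.segment(name)
        frames.append(
            pd.DataFrame(
                {"segment": name, "position_nm": seg[:, 0], "force_pN": seg[:, 1]}
            )
        )
    pd.concat(frames).to_csv(path, sep="\t", index=False)
    meta_path = _sidecar_path(path)
    if curve.meta:
        meta_path.write_text(json.dumps(curve.meta, indent=2, default=str))
    return path


def read_force_curve(path: str | Path) -> ForceCurve:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(CURVE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"curve TSV {path} missing columns: {sorted(missing)}")
    meta: dict[str, Any] = {}
    meta_path = _sidecar_path(path)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    segs = {}
    for name in ("approach", "retract"):
        sub = df[df["segment"] == name]
        if sub.empty:
            raise ValueError(f"curve TSV {path} has no '{name}' segment")
        segs[name] = sub[["position_nm", "force_pN"]].to_numpy(dtype=float)
    return ForceCurve(segs["approach"], segs["retract"], meta)


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a grayscale image as TIFF, preserving integer dtype."""
    path = Path(path)
    tifffile.imwrite(path, image)
    return path


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(Path(path)))
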