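"""File formats: PLY/XYZ point clouds, TIFF rasters with a georeferencing
sidecar, CSV tables.

Rasters are written as one single-band TIFF per spectral band plus thermal,
with a JSON sidecar (``<name>.tif.json``) carrying the affine georeferencing
(origin and pixel size in metres) so that a stack can be rebuilt losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .geometry import PointCloud
from .imagery import BANDS_NM, BandStack, RasterTransform

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_raster",
    "write_raster",
    "read_band_stack",
    "write_band_stack",
    "read_tree_centers",
    "read_phenotype_table",
]


class FormatError(ValueError):
    """Unsupported or malformed input file."""


def read_point_cloud(path, tree_id: str | None = None) -> PointCloud:
    """Read a crown point cloud from PLY (ascii or binary) or
    whitespace-delimited XYZ (coordinates in metres)."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        try:
            geom = trimesh.load(str(path), process=False)
        except Exception as exc:
            raise FormatError(f"cannot parse PLY file {path}: {exc}") from exc
        pts = np.asarray(geom.vertices, dtype=float)
    elif path.suffix.lower() in {".xyz", ".txt"}:
        try:
            pts = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"non-numeric record in {path}: {exc}") from exc
        if pts.shape[1] < 3:
            raise FormatError(f"{path}: expected >= 3 columns, got {pts.shape[1]}")
        pts = pts[:, :3]
    else:
        raise FormatError(f"unsupported point-cloud extension: {path.suffix!r}")
    return PointCloud(points=pts, tree_id=tree_id or path.stem)


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Write a crown as ASCII PLY (x/y/z float vertices)."""
    path = Path(path)
    if path.suffix.lower() != ".ply":
        raise FormatError(f"point clouds are written as .ply, got {path.suffix!r}")
    pc = trimesh.PointCloud(np.asarray(cloud.points, dtype=float))
    data = trimesh.exchange.ply.export_ply(pc, encoding="ascii")
    path.write_bytes(data)


def write_raster(array: np.ndarray, transform: RasterTransform, path) -> None:
    """Write one raster band as TIFF plus a JSON georeferencing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    sidecar = {
        "x_origin": transform.x_origin,
        "y_origin": transform.y_origin,
        "pixel_size": transform.pixel_size,
        "units": "m",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_raster(path):
    """Read a single-band TIFF and its sidecar; return (array, transform)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    array = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing georeferencing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    transform = RasterTransform(
        x_origin=meta["x_origin"], y_origin=meta["y_origin"], pixel_size=meta["pixel_size"]
    )
    return array, transform


def write_band_stack(stack: BandStack, directory, prefix: str = "band") -> dict:
    """Write every band of the stack as ``<prefix>_<nm>.tif``; return the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for nm, arr in sorted(stack.bands.items()):
        p = directory / f"{prefix}_{nm}.tif"
        write_raster(arr, stack.transform, p)
        paths[nm] = p
    return paths


def read_band_stack(directory, prefix: str = "band", bands=BANDS_NM) -> BandStack:
    """Rebuild a band stack from per-band TIFFs written by
    :func:`write_band_stack`; shapes and transforms must agree."""
    directory = Path(directory)
    arrays, transforms = {}, set()
    for nm in bands:
        arr, tr = read_raster(directory / f"{prefix}_{nm}.tif")
        arrays[nm] = arr
        transforms.add(tr)
    if len(transforms) > 1:
        raise FormatError(f"bands disagree in georeferencing: {transforms}")
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) > 1:
        raise FormatError(f"band shape mismatch across the stack: {sorted(shapes)}")
    return BandStack(bands=arrays, transform=transforms.pop())


def read_tree_centers(path) -> pd.DataFrame:
    """CSV of tree centres with columns tree_id, x, y (metres)."""
    df = pd.read_csv(path)
    missing = {"tree_id", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_phenotype_table(path, value_col: str = "value") -> pd.DataFrame:
    """Long-format phenotype CSV; non-numeric trait values raise with the
    offending line number."""
    df = pd.read_csv(path)
    if value_col not in df.columns:
        raise FormatError(f"{path}: missing column {value_col!r}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    bad = values.isna() & df[value_col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after the header
        raise FormatError(
            f"{path}: non-numeric {value_col!r} value "
            f"{df.loc[bad, value_col].iloc[0]!r} at line {line}"
        )
    df[value_col] = values
    return df
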