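"""Raster and polygon I/O on the abstract metric grid.

Grids are row-major numpy arrays with cell (0, 0) at the top-left and
1-ha (100 m) square cells unless configured otherwise. Map coordinates put
``x = column`` and ``y = row`` (y increases downward), so the cell at
``(row, col)`` occupies the unit square ``[col, col+1] x [row, row+1]`` and
has its center at ``(col + 0.5, row + 0.5)``.

Rasters are stored as single-band TIFFs (written with tifffile); vector
data as GeoJSON FeatureCollections read into shapely geometries.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import mapping, shape


def write_grid(path, array, tags: dict | None = None) -> None:
    """Write a single-band grid as TIFF; optional metadata as JSON tag."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    meta = {"description": json.dumps(tags)} if tags else {}
    tifffile.imwrite(path, arr, **meta)


def read_grid(path, dtype=None) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if dtype is not None:
        arr = arr.astype(dtype)
    return arr


def write_polygons(path, geometries, properties) -> None:
    """Write shapely geometries with per-feature property dicts as GeoJSON."""
    features = [
        {"type": "Feature", "geometry": mapping(geom), "properties": props}
        for geom, props in zip(geometries, properties, strict=True)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}))


def read_polygons(path):
    """Read a GeoJSON FeatureCollection -> (geometries, properties) lists."""
    doc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties") or {} for f in doc["features"]]
    return geoms, props


def cell_centers(shape_):
    """(x, y) map coordinates of all cell centers of a grid shape."""
    rows, cols = shape_
    y, x = np.mgrid[0:rows, 0:cols]
    return x + 0.5, y + 0.5


def check_registration(*grids) -> None:
    """Raise if the grids do not share a common shape."""
    shapes = {np.asarray(g).shape for g in grids}
    if len(shapes) > 1:
        raise ValueError(f"grids are not co-registered: shapes {sorted(shapes)}")
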