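"""File round-trips: TIFF rasters with world-file sidecars, GeoJSON ROIs, CSV tables.

Rasters are written as plain TIFF plus an ESRI world file (``.tfw``) carrying the
affine georeferencing (pixel size and the world coordinate of the upper-left
pixel centre).  This keeps every artifact readable by standard GIS tools without
requiring a GDAL stack at run time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd
import tifffile

from .raster import Raster, ROIBox

__all__ = [
    "write_raster",
    "read_raster",
    "write_rois_geojson",
    "read_rois_geojson",
    "read_rois_csv",
    "write_truth_csv",
    "read_truth_csv",
    "file_checksum",
]


def write_raster(path: str | Path, r: Raster) -> Path:
    """Write a raster as TIFF + ``.tfw`` world-file sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, r.values)
    g = r.gds_m
    # world file lines: x-size, rot, rot, -y-size, x of UL pixel centre, y of UL pixel centre
    tfw = path.with_suffix(path.suffix + ".tfw")
    tfw.write_text(
        "\n".join(f"{v:.10f}" for v in (g, 0.0, 0.0, -g, r.origin[0], r.origin[1])) + "\n"
    )
    return path


def read_raster(path: str | Path, nodata: float | None = None) -> Raster:
    path = Path(path)
    values = tifffile.imread(path)
    tfw = path.with_suffix(path.suffix + ".tfw")
    if tfw.exists():
        a, _, _, e, ox, oy = (float(line) for line in tfw.read_text().split())
        gds_cm = a * 100.0
        origin = (ox, oy)
    else:
        gds_cm, origin = 1.0, (0.0, 0.0)
    return Raster(values, gds_cm, origin, nodata)


def write_rois_geojson(path: str | Path, rois: Iterable[ROIBox]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features = []
    for roi in rois:
        ring = [
            [roi.xmin, roi.ymin],
            [roi.xmax, roi.ymin],
            [roi.xmax, roi.ymax],
            [roi.xmin, roi.ymax],
            [roi.xmin, roi.ymin],
        ]
        features.append(
            {
                "type": "Feature",
                "properties": {"plot_id": roi.plot_id},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
    return path


def read_rois_geojson(path: str | Path) -> List[ROIBox]:
    data = json.loads(Path(path).read_text())
    rois = []
    for feat in data["features"]:
        coords = np.asarray(feat["geometry"]["coordinates"][0], dtype=float)
        rois.append(
            ROIBox(
                plot_id=str(feat["properties"]["plot_id"]),
                xmin=float(coords[:, 0].min()),
                ymin=float(coords[:, 1].min()),
                xmax=float(coords[:, 0].max()),
                ymax=float(coords[:, 1].max()),
            )
        )
    return rois


def read_rois_csv(path: str | Path) -> List[ROIBox]:
    """CSV fallback with columns plot_id, xmin, ymin, xmax, ymax."""
    df = pd.read_csv(path)
    return [
        ROIBox(str(row.plot_id), float(row.xmin), float(row.ymin), float(row.xmax), float(row.ymax))
        for row in df.itertuples()
    ]


TRUTH_COLUMNS = [
    "plot_id",
    "repeat",
    "treatment",
    "period",
    "cover_fraction",
    "height_cm",
    "agb_kg_hm2",
]


def write_truth_csv(path: str | Path, truth: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS, float_format="%.6f")
    return path


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"plot_id": str})


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
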