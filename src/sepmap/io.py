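"""File formats: rasters (GeoTIFF-style TIFF), vectors (GeoJSON), tables.

Rasters are written as single-band TIFFs with the grid geometry, CRS,
nodata value and class legend stored as a JSON document in the TIFF
ImageDescription tag, so write-then-read round-trips are bit-identical for
integer rasters and exact to float representation otherwise. Vectors go
through GeoJSON FeatureCollections (shapely geometries + plain property
dicts). Shapefile input is out of scope; GeoJSON is the interchange format.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from sepmap.grid import GridGeometry, Raster
from sepmap.points import SurveyPoints

_META_KEY = "sepmap_meta"


def write_raster(path: str | Path, raster: Raster) -> Path:
    path = Path(path)
    meta = {
        "grid": raster.grid.to_dict(),
        "nodata": None
        if raster.nodata is None
        else ("nan" if isinstance(raster.nodata, float) and np.isnan(raster.nodata) else raster.nodata),
        "legend": {str(k): v for k, v in raster.legend.items()},
    }
    # prefix keeps tifffile from misreading the JSON as its own shaped metadata
    tifffile.imwrite(
        path,
        raster.data,
        description="sepmap " + json.dumps({_META_KEY: meta}, sort_keys=True),
        metadata=None,
    )
    return path


def read_raster(path: str | Path) -> Raster:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is None:
            raise ValueError(f"{path} carries no grid metadata")
        text = desc.value
        meta = json.loads(text.removeprefix("sepmap "))[_META_KEY]
    nodata = meta["nodata"]
    if nodata == "nan":
        nodata = float("nan")
    legend = {int(k): v for k, v in meta.get("legend", {}).items()}
    return Raster(data, GridGeometry.from_dict(meta["grid"]), nodata, legend)


def write_vector(
    path: str | Path,
    geometries: list,
    properties: list[dict] | None = None,
    crs: str | None = None,
) -> Path:
    path = Path(path)
    properties = properties or [{} for _ in geometries]
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geometries, properties)
        ],
    }
    if crs:
        fc["crs"] = {"type": "name", "properties": {"name": crs}}
    path.write_text(json.dumps(fc))
    return path


def read_vector(path: str | Path) -> tuple[list, list[dict]]:
    fc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties") or {} for f in fc["features"]]
    return geoms, props


def write_survey_points(path: str | Path, points: SurveyPoints, crs: str | None = None) -> Path:
    from shapely.geometry import Point

    geoms = [Point(x, y) for x, y in zip(*points.xy)]
    props = [
        {"true_class": int(c), "role": r}
        for c, r in zip(points.labels, points.df["role"])
    ]
    return write_vector(path, geoms, props, crs=crs)


def read_survey_points(path: str | Path) -> SurveyPoints:
    geoms, props = read_vector(path)
    return SurveyPoints.from_arrays(
        [g.x for g in geoms],
        [g.y for g in geoms],
        [p["true_class"] for p in props],
        [p["role"] for p in props],
    )


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def write_json_report(path: str | Path, report: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True))
    return path


def write_table(path: str | Path, frame: pd.DataFrame) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
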