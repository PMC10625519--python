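"""File formats: GeoTIFF rasters, GeoJSON/CSV sample tables, model bundles.

Rasters are single-band uint8 GeoTIFFs (class codes 0/1/2, nodata 255) with
georeferencing carried in the standard tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory) plus a JSON ImageDescription for the equal-area flag; the
tag layer sits on tifffile.  Published products are named
``<adcode>_<year>.tif`` by administrative-division code.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
import tifffile

from .constants import BAND_NAMES
from .types import CoarseMask, LabelRaster, PixelTimeSeries, SampleRecord

__all__ = [
    "product_filename",
    "parse_product_filename",
    "write_label_raster",
    "read_label_raster",
    "write_coarse_mask",
    "read_coarse_mask",
    "write_samples_geojson",
    "read_samples_geojson",
    "write_samples_csv",
    "read_samples_csv",
    "write_series_table",
    "read_series_table",
    "save_model_bundle",
    "load_model_bundle",
    "file_sha256",
]

_PRODUCT_RE = re.compile(r"^(\d+)_(\d{4})\.tif$")
BUNDLE_FORMAT_VERSION = 1


def product_filename(adcode: int, year: int) -> str:
    """Per-province product name, ``<adcode>_<year>.tif``."""
    if not isinstance(adcode, (int, np.integer)) or adcode <= 0:
        raise ValueError("adcode must be a positive integer")
    if not isinstance(year, (int, np.integer)) or not 1000 <= year <= 9999:
        raise ValueError("year must be a 4-digit year")
    return f"{int(adcode)}_{int(year)}.tif"


def parse_product_filename(name: str) -> tuple[int, int]:
    m = _PRODUCT_RE.match(Path(name).name)
    if not m:
        raise ValueError(f"not a product filename: {name!r}")
    return int(m.group(1)), int(m.group(2))


def _epsg_of(crs: str) -> int:
    m = re.match(r"^EPSG:(\d+)$", crs, flags=re.IGNORECASE)
    return int(m.group(1)) if m else 32767  # 32767 = user-defined


def _geo_extratags(cell_size: float, origin, crs: str, description: dict):
    epsg = _epsg_of(crs)
    geokeys = [1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg]
    return [
        (33550, "d", 3, (cell_size, cell_size, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)),
        (34735, "H", len(geokeys), tuple(geokeys)),
    ]


def _read_geo(page) -> tuple[float, tuple[float, float], str, dict]:
    tags = page.tags
    scale = tags[33550].value if 33550 in tags else (1.0, 1.0, 0.0)
    tie = tags[33922].value if 33922 in tags else (0, 0, 0, 0.0, 0.0, 0.0)
    desc = {}
    if 270 in tags:
        try:
            desc = json.loads(tags[270].value)
        except (TypeError, ValueError):
            desc = {}
    crs = desc.get("crs", "")
    if not crs and 34735 in tags:
        keys = tags[34735].value
        for i in range(4, len(keys), 4):
            if keys[i] == 3072 and keys[i + 3] != 32767:
                crs = f"EPSG:{keys[i + 3]}"
    return float(scale[0]), (float(tie[3]), float(tie[4])), crs, desc


def write_label_raster(path, raster: LabelRaster) -> Path:
    path = Path(path)
    desc = {
        "crs": raster.crs,
        "equal_area": bool(raster.equal_area),
        "nodata": int(raster.nodata),
    }
    tifffile.imwrite(
        path,
        raster.data.astype(np.uint8),
        description=json.dumps(desc),
        extratags=_geo_extratags(raster.cell_size, raster.origin, raster.crs, desc),
    )
    return path


def read_label_raster(path) -> LabelRaster:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        cell, origin, crs, desc = _read_geo(page)
    return LabelRaster(
        data.astype(np.uint8),
        cell_size=cell,
        origin=origin,
        crs=crs or "EPSG:32767",
        equal_area=bool(desc.get("equal_area", False)),
        nodata=int(desc.get("nodata", 255)),
    )


def write_coarse_mask(path, mask: CoarseMask) -> Path:
    path = Path(path)
    desc = {"crs": mask.crs, "coarse_mask": True}
    tifffile.imwrite(
        path,
        mask.data.astype(np.uint8),
        description=json.dumps(desc),
        extratags=_geo_extratags(mask.cell_size, mask.origin, mask.crs, desc),
    )
    return path


def read_coarse_mask(path) -> CoarseMask:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray()
        cell, origin, crs, _ = _read_geo(page)
    return CoarseMask(data.astype(bool), cell_size=cell, origin=origin,
                      crs=crs or "EPSG:32767")


def write_samples_geojson(path, records: list[SampleRecord]) -> Path:
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r.lon, r.lat]},
            "properties": {
                "id": r.id,
                "zone": r.zone,
                "year": r.year,
                "class": r.class_label,
                "method": r.method,
            },
        }
        for r in records
    ]
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return path


def read_samples_geojson(path) -> list[SampleRecord]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc.get("features", []):
        lon, lat = feat["geometry"]["coordinates"][:2]
        p = feat["properties"]
        out.append(
            SampleRecord(
                id=str(p["id"]),
                lon=float(lon),
                lat=float(lat),
                zone=str(p["zone"]),
                year=int(p["year"]),
                class_label=str(p["class"]),
                method=str(p["method"]),
            )
        )
    return out


def write_samples_csv(path, records: list[SampleRecord]) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "lon": r.lon,
                "lat": r.lat,
                "zone": r.zone,
                "year": r.year,
                "class": r.class_label,
                "method": r.method,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)
    return path


def read_samples_csv(path) -> list[SampleRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SampleRecord(
            id=str(row["id"]),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            zone=str(row["zone"]),
            year=int(row["year"]),
            class_label=str(row["class"]),
            method=str(row["method"]),
        )
        for _, row in df.iterrows()
    ]


def write_series_table(path, series: dict[str, PixelTimeSeries]) -> Path:
    """Per-pixel sequence table: pixel_id, doy, one column per band, cloud_flag."""
    rows = []
    for pid, s in series.items():
        for i in range(len(s)):
            row = {"pixel_id": pid, "doy": int(s.doy[i])}
            row.update({b: s.bands[i, j] for j, b in enumerate(BAND_NAMES)})
            row["cloud_flag"] = bool(s.cloud_flag[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_series_table(path) -> dict[str, PixelTimeSeries]:
    df = pd.read_csv(path)
    out = {}
    for pid, grp in df.groupby("pixel_id", sort=False):
        grp = grp.sort_values("doy")
        out[str(pid)] = PixelTimeSeries(
            grp["doy"].to_numpy(),
            grp[list(BAND_NAMES)].to_numpy(dtype=float),
            grp["cloud_flag"].to_numpy(dtype=bool),
        )
    return out


def save_model_bundle(directory, zone_model) -> Path:
    """Persist a fitted ZoneModel as a versioned on-disk bundle."""
    from .classifiers import GRUCenterLossClassifier, ZoneRandomForestClassifier

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model = zone_model.model
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "zone_id": zone_model.zone_id,
        "model_kind": zone_model.model_kind,
        "params": model.get_params(),
        "classes": [str(c) for c in model.classes_],
        "metadata": _jsonable(
            {k: v for k, v in zone_model.metadata.items() if k != "test_records"}
        ),
    }
    if isinstance(model, GRUCenterLossClassifier):
        np.savez(
            directory / "weights.npz",
            centers=model.centers_,
            **{f"p_{k}": v for k, v in model.params_.items()},
        )
        manifest["weights"] = "weights.npz"
    elif isinstance(model, ZoneRandomForestClassifier):
        joblib.dump(model.estimator_, directory / "forest.joblib")
        manifest["weights"] = "forest.joblib"
    else:
        raise TypeError(f"cannot serialize model of type {type(model)!r}")
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_model_bundle(directory):
    """Reconstruct a ZoneModel; verifies the bundle format and weight shapes."""
    from .classifiers import (
        GRUCenterLossClassifier,
        ZoneModel,
        ZoneRandomForestClassifier,
    )

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    if manifest["format_version"] != BUNDLE_FORMAT_VERSION:
        raise ValueError(
            f"unsupported bundle format {manifest['format_version']}"
        )
    classes = np.array(manifest["classes"])
    if manifest["model_kind"] == "recurrent_net":
        clf = GRUCenterLossClassifier(**manifest["params"])
        with np.load(directory / "weights.npz") as z:
            clf.params_ = {
                k[2:]: z[k] for k in z.files if k.startswith("p_")
            }
            clf.centers_ = z["centers"]
        if clf.params_["b_z0"].shape[0] != clf.hidden_size:
            raise ValueError("bundle weights do not match the stored config")
        clf.classes_ = classes
    elif manifest["model_kind"] == "random_forest":
        clf = ZoneRandomForestClassifier(**manifest["params"])
        clf.estimator_ = joblib.load(directory / "forest.joblib")
        clf.classes_ = clf.estimator_.classes_
        clf.metadata_ = manifest["metadata"]
    else:
        raise ValueError(f"unknown model kind {manifest['model_kind']!r}")
    return ZoneModel(
        manifest["zone_id"], manifest["model_kind"], clf, manifest["metadata"]
    )


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-safe values."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        try:
            return _jsonable(asdict(obj))
        except TypeError:
            return str(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
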