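"""Readers and writers for the formats the pipeline touches.

Three cube dialects are supported behind one internal data model:

* ``envi`` — band-sequential (BSQ) raw int16 payload with a plain-text
  ``.hdr`` companion carrying the wavelength array and the data-ignore
  value; reflectance is stored as scaled integers (factor 10,000,
  sentinel -9999).
* ``geotiff`` — a single multi-band TIFF (one raster band per spectral
  band, same integer scaling) with georeferencing and the wavelength axis
  in a JSON metadata block.
* ``npz`` — an internal fixture-archive dialect (compressed array
  container with a small manifest) so tests can round-trip cubes without
  any geospatial system library.

Readers never repair inconsistent metadata silently: a header whose
declared shape disagrees with the payload size is an error, not a
truncation.
"""

from __future__ import annotations

import json
import os
import re

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .types import (
    EndmemberLibrary,
    FractionStack,
    ReferencePoints,
    SpectralCube,
    NODATA_SENTINEL,
    REFLECTANCE_SCALE,
)

__all__ = [
    "write_cube",
    "read_cube",
    "write_fraction_maps",
    "read_fraction_maps",
    "write_points",
    "read_points",
    "write_library",
    "read_library",
]

_DIALECTS = ("envi", "geotiff", "npz")


def _cube_meta(cube: SpectralCube) -> dict:
    return {
        "wavelengths_nm": cube.wavelengths_nm.tolist(),
        "band_valid": cube.band_valid.astype(int).tolist(),
        "scale_factor": REFLECTANCE_SCALE,
        "nodata": NODATA_SENTINEL,
        "pixel_size_m": cube.pixel_size_m,
        "origin_xy": list(cube.origin_xy),
        "crs_label": cube.crs_label,
    }


def _to_scaled_int(cube: SpectralCube) -> np.ndarray:
    data = np.round(cube.reflectance * REFLECTANCE_SCALE).astype(np.int16)
    data[~cube.pixel_valid, :] = NODATA_SENTINEL
    return data


def _from_scaled_int(data, meta) -> SpectralCube:
    scale = meta.get("scale_factor", REFLECTANCE_SCALE)
    sentinel = meta.get("nodata", NODATA_SENTINEL)
    pixel_valid = ~np.any(data == sentinel, axis=2)
    reflectance = data.astype(np.float64) / scale
    return SpectralCube(
        reflectance=reflectance,
        wavelengths_nm=np.asarray(meta["wavelengths_nm"], dtype=np.float64),
        band_valid=np.asarray(
            meta.get("band_valid", np.ones(data.shape[2])), dtype=bool
        ),
        pixel_valid=pixel_valid,
        pixel_size_m=meta.get("pixel_size_m", 1.0),
        origin_xy=tuple(meta.get("origin_xy", (0.0, 0.0))),
        crs_label=meta.get("crs_label", "local"),
    )


# --------------------------------------------------------------------------
# ENVI dialect


def _envi_header_path(path: str) -> str:
    return path + ".hdr"


def _write_envi(cube: SpectralCube, path: str):
    data = _to_scaled_int(cube)  # (rows, cols, bands)
    bsq = np.ascontiguousarray(np.moveaxis(data, 2, 0))  # (bands, rows, cols)
    bsq.tofile(path)
    wl = ", ".join(f"{w:.1f}" for w in cube.wavelengths_nm)
    bbl = ", ".join("1" if v else "0" for v in cube.band_valid)
    header = (
        "ENVI\n"
        "description = {grassunmix reflectance cube}\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 2\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"data ignore value = {NODATA_SENTINEL}\n"
        f"reflectance scale factor = {REFLECTANCE_SCALE}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
        f"bbl = {{ {bbl} }}\n"
        f"map info = {{grassunmix, 1, 1, {cube.origin_xy[0]}, "
        f"{cube.origin_xy[1]}, {cube.pixel_size_m}, {cube.pixel_size_m}}}\n"
        f"coordinate system string = {{{cube.crs_label}}}\n"
    )
    with open(_envi_header_path(path), "w") as fh:
        fh.write(header)


def _parse_envi_header(text: str) -> dict:
    # fold brace-delimited arrays onto one logical line, then parse key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def _read_envi(path: str) -> SpectralCube:
    hdr_path = _envi_header_path(path)
    if not os.path.exists(hdr_path):
        raise DataError(f"missing ENVI header {hdr_path}")
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
    except KeyError as exc:
        raise DataError(f"ENVI header missing required field {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise DataError("only BSQ interleave is supported")
    if dtype_code != 2:
        raise DataError(f"unsupported ENVI data type code {dtype_code}")
    if "wavelength" not in fields:
        raise DataError("ENVI header lacks a wavelength array")
    wl = np.array(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",")]
    )
    if wl.size != bands:
        raise DataError(
            f"header declares {bands} bands but lists {wl.size} wavelengths"
        )
    expected = rows * cols * bands * np.dtype(np.int16).itemsize
    actual = os.path.getsize(path)
    if actual != expected:
        raise DataError(
            f"ENVI payload is {actual} bytes but the header implies {expected} "
            f"({rows} lines x {cols} samples x {bands} bands of int16)"
        )
    bsq = np.fromfile(path, dtype=np.int16).reshape(bands, rows, cols)
    data = np.moveaxis(bsq, 0, 2)
    meta = {
        "wavelengths_nm": wl,
        "nodata": float(fields.get("data ignore value", NODATA_SENTINEL)),
        "scale_factor": float(
            fields.get("reflectance scale factor", REFLECTANCE_SCALE)
        ),
    }
    if "bbl" in fields:
        meta["band_valid"] = np.array(
            [int(float(v)) for v in fields["bbl"].strip("{} ").split(",")]
        )
    if "map info" in fields:
        parts = [p.strip() for p in fields["map info"].strip("{} ").split(",")]
        if len(parts) >= 6:
            meta["origin_xy"] = (float(parts[3]), float(parts[4]))
            meta["pixel_size_m"] = float(parts[5])
    if "coordinate system string" in fields:
        meta["crs_label"] = fields["coordinate system string"].strip("{}")
    return _from_scaled_int(data, meta)


# --------------------------------------------------------------------------
# GeoTIFF dialect (tifffile carrier; georeferencing in a JSON block)


def _write_geotiff(cube: SpectralCube, path: str):
    data = _to_scaled_int(cube)  # (rows, cols, bands)
    pages = np.ascontiguousarray(np.moveaxis(data, 2, 0))  # (bands, rows, cols)
    tifffile.imwrite(
        path,
        pages,
        photometric="minisblack",
        description=json.dumps(_cube_meta(cube)),
    )


def _read_geotiff(path: str) -> SpectralCube:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise DataError(
            "GeoTIFF lacks the JSON metadata block carrying the wavelength axis"
        ) from exc
    if pages.ndim == 2:
        pages = pages[None]
    data = np.moveaxis(pages, 0, 2)
    if data.shape[2] != len(meta["wavelengths_nm"]):
        raise DataError(
            f"TIFF has {data.shape[2]} bands but metadata lists "
            f"{len(meta['wavelengths_nm'])} wavelengths"
        )
    return _from_scaled_int(data, meta)


# --------------------------------------------------------------------------
# fixture-archive dialect


def _write_npz(cube: SpectralCube, path: str):
    np.savez_compressed(
        path,
        reflectance_scaled=_to_scaled_int(cube),
        manifest=np.array(json.dumps(_cube_meta(cube))),
    )


def _read_npz(path: str) -> SpectralCube:
    with np.load(path, allow_pickle=False) as archive:
        if "manifest" not in archive or "reflectance_scaled" not in archive:
            raise DataError("fixture archive lacks manifest or payload")
        meta = json.loads(str(archive["manifest"]))
        data = archive["reflectance_scaled"]
    return _from_scaled_int(data, meta)


def write_cube(cube: SpectralCube, path: str, dialect: str = "envi") -> str:
    """Write a cube in the named dialect; returns the written path."""
    if dialect not in _DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    {"envi": _write_envi, "geotiff": _write_geotiff, "npz": _write_npz}[dialect](
        cube, path
    )
    return path


def read_cube(path: str, dialect: str = None) -> SpectralCube:
    """Read a cube; the dialect is inferred from the extension if omitted."""
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    if dialect is None:
        ext = os.path.splitext(path)[1].lower()
        dialect = {".tif": "geotiff", ".tiff": "geotiff", ".npz": "npz"}.get(
            ext, "envi"
        )
    if dialect not in _DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}; choose from {_DIALECTS}")
    return {"envi": _read_envi, "geotiff": _read_geotiff, "npz": _read_npz}[dialect](
        path
    )


# --------------------------------------------------------------------------
# fraction maps (float32 multiband TIFF, NaN no-data)


def write_fraction_maps(stack: FractionStack, path: str) -> str:
    """One float raster band per class; invalid pixels become NaN."""
    data = stack.fractions.astype(np.float32).copy()
    data[:, ~stack.pixel_valid] = np.nan
    rmse = stack.residual_rmse.astype(np.float32).copy()
    rmse[~stack.pixel_valid] = np.nan
    meta = {
        "class_names": list(stack.class_names),
        "mode": stack.mode,
        "pixel_size_m": stack.pixel_size_m,
        "origin_xy": list(stack.origin_xy),
        "crs_label": stack.crs_label,
        "last_band_is_rmse": True,
    }
    tifffile.imwrite(
        path,
        np.concatenate([data, rmse[None]], axis=0),
        photometric="minisblack",
        description=json.dumps(meta),
    )
    return path


def read_fraction_maps(path: str) -> FractionStack:
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise DataError("fraction raster lacks its JSON metadata block") from exc
    class_names = meta["class_names"]
    data = pages.astype(np.float64)
    if meta.get("last_band_is_rmse"):
        rmse = data[-1]
        data = data[: len(class_names)]
    else:
        rmse = np.zeros(data.shape[1:])
    pixel_valid = ~np.any(np.isnan(data), axis=0)
    rmse = np.where(pixel_valid, rmse, 0.0)
    return FractionStack(
        fractions=np.where(pixel_valid, data, np.nan),
        class_names=class_names,
        residual_rmse=rmse,
        mode=meta.get("mode", "fcls"),
        pixel_valid=pixel_valid,
        pixel_size_m=meta.get("pixel_size_m", 1.0),
        origin_xy=tuple(meta.get("origin_xy", (0.0, 0.0))),
        crs_label=meta.get("crs_label", "local"),
    )


# --------------------------------------------------------------------------
# points (CSV and GeoJSON)


def write_points(points: ReferencePoints, path: str) -> str:
    """CSV (header ``x,y,label``) or GeoJSON, chosen by extension."""
    if path.lower().endswith((".geojson", ".json")):
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [x, y]},
                "properties": {"label": lab},
            }
            for x, y, lab in zip(points.x, points.y, points.labels)
        ]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    else:
        pd.DataFrame(
            {"x": points.x, "y": points.y, "label": points.labels}
        ).to_csv(path, index=False)
    return path


def read_points(path: str, class_list=None) -> ReferencePoints:
    """Read points from CSV or GeoJSON; empty files yield empty collections.

    With ``class_list`` given, a label outside the list is an error naming
    the offending row.
    """
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    if path.lower().endswith((".geojson", ".json")):
        with open(path) as fh:
            doc = json.load(fh)
        xs, ys, labels = [], [], []
        for feat in doc.get("features", []):
            xs.append(float(feat["geometry"]["coordinates"][0]))
            ys.append(float(feat["geometry"]["coordinates"][1]))
            labels.append(str(feat["properties"]["label"]))
    else:
        table = pd.read_csv(path)
        missing = {"x", "y", "label"} - set(table.columns)
        if missing:
            raise DataError(f"point CSV lacks column(s) {sorted(missing)}")
        bad = table[["x", "y"]].apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any():
            row = int(bad.isna().any(axis=1).idxmax())
            raise DataError(f"non-numeric coordinate at row {row}")
        xs, ys, labels = (
            table["x"].to_numpy(float),
            table["y"].to_numpy(float),
            [str(v) for v in table["label"]],
        )
    return ReferencePoints(
        x=np.asarray(xs, dtype=float),
        y=np.asarray(ys, dtype=float),
        labels=labels,
        class_list=list(class_list) if class_list is not None else None,
    )


# --------------------------------------------------------------------------
# endmember library (wide CSV)


def write_library(lib: EndmemberLibrary, path: str) -> str:
    """Wide CSV: ``wavelength_nm`` column then one column per class."""
    table = pd.DataFrame({"wavelength_nm": lib.wavelengths_nm})
    for i, name in enumerate(lib.class_names):
        table[name] = lib.spectra[i]
    table["band_valid"] = lib.band_valid.astype(int)
    table.to_csv(path, index=False)
    return path


def read_library(path: str, class_order=None) -> EndmemberLibrary:
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    table = pd.read_csv(path)
    if "wavelength_nm" not in table.columns:
        raise DataError("library CSV lacks a wavelength_nm column")
    band_valid = None
    if "band_valid" in table.columns:
        band_valid = table.pop("band_valid").to_numpy(bool)
    classes = [c for c in table.columns if c != "wavelength_nm"]
    if class_order is not None:
        missing = set(class_order) - set(classes)
        if missing:
            raise DataError(f"library CSV lacks class column(s) {sorted(missing)}")
        classes = list(class_order)
    return EndmemberLibrary(
        spectra=table[classes].to_numpy(float).T,
        class_names=classes,
        wavelengths_nm=table["wavelength_nm"].to_numpy(float),
        band_valid=band_valid,
    )
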