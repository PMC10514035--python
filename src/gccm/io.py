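"""File I/O: rasters (ESRI ASCII grid, GeoTIFF), polygons (GeoJSON,
CSV attribute + edge-list), results tables, verdict JSON, and the
convergence plot.

Inputs must be co-registered: both variables of a pair on the same grid or
the same set of polygon units.  Georeference metadata is carried through
untouched.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .errors import GCCMError
from .fields import PolygonField, RasterField
from .spatial import queen_adjacency

__all__ = [
    "read_raster",
    "write_raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geotiff",
    "write_geotiff",
    "read_polygon_geojson",
    "read_polygon_csv",
    "write_results_csv",
    "write_verdict_json",
    "plot_convergence",
]

GDAL_NODATA_TAG = 42113


def read_raster(path) -> RasterField:
    """Read a raster by extension: .asc/.grd/.txt ASCII grid, .tif/.tiff GeoTIFF."""
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".grd", ".txt"):
        return read_ascii_grid(path)
    if suffix in (".tif", ".tiff"):
        return read_geotiff(path)
    raise GCCMError(f"unsupported raster format {suffix!r}")


def write_raster(fld: RasterField, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix in (".asc", ".grd", ".txt"):
        write_ascii_grid(fld, path)
    elif suffix in (".tif", ".tiff"):
        write_geotiff(fld, path)
    else:
        raise GCCMError(f"unsupported raster format {suffix!r}")


def read_ascii_grid(path) -> RasterField:
    """ESRI ASCII grid; the NODATA_VALUE tag maps to missing."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    if "ncols" not in header or "nrows" not in header:
        raise GCCMError(f"{path}: missing ncols/nrows header")
    data = np.loadtxt(lines[i:].__iter__(), dtype=float, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    if "nodata_value" in header:
        data[data == header["nodata_value"]] = np.nan
    transform = None
    if "cellsize" in header:
        cs = header["cellsize"]
        x0 = header.get("xllcorner", header.get("xllcenter", 0.0))
        y0 = header.get("yllcorner", header.get("yllcenter", 0.0))
        transform = (cs, 0.0, x0, 0.0, -cs, y0 + nrows * cs)
    return RasterField(data, transform=transform)


def write_ascii_grid(fld: RasterField, path, nodata: float = -9999.0) -> None:
    vals = fld.values.copy()
    vals[~np.isfinite(vals)] = nodata
    cellsize, x0, ytop = 1.0, 0.0, float(fld.nrows)
    if fld.transform is not None:
        cellsize, _, x0, _, _, ytop = fld.transform
    with open(path, "w") as fh:
        fh.write(f"ncols {fld.ncols}\n")
        fh.write(f"nrows {fld.nrows}\n")
        fh.write(f"xllcorner {x0}\n")
        fh.write(f"yllcorner {ytop - fld.nrows * cellsize}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_geotiff(path) -> RasterField:
    """Single-band GeoTIFF via tifffile; honors the GDAL nodata tag."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        if data.ndim == 3:
            data = data[..., 0]
        tag = page.tags.get(GDAL_NODATA_TAG)
        if tag is not None:
            try:
                nodata = float(str(tag.value).strip())
                data[data == nodata] = np.nan
            except ValueError:
                pass
    return RasterField(data)


def write_geotiff(fld: RasterField, path, nodata: float = -9999.0) -> None:
    import tifffile

    vals = fld.values.astype(np.float32).copy()
    vals[~np.isfinite(vals)] = nodata
    tifffile.imwrite(
        path,
        vals,
        extratags=[(GDAL_NODATA_TAG, "s", 0, str(nodata), True)],
    )


def read_polygon_geojson(path, value_field: str, id_field: str | None = None) -> PolygonField:
    """GeoJSON FeatureCollection -> PolygonField with queen contiguity.

    Unit ids come from ``id_field`` (or the feature ``id``, else the
    feature index).  A feature lacking the value attribute gets a missing
    value; the run proceeds.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if not feats:
        raise GCCMError(f"{path}: no features")
    ids, values, geoms = [], [], []
    for i, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if id_field is not None:
            uid = props[id_field]
        else:
            uid = feat.get("id", i)
        v = props.get(value_field)
        ids.append(uid)
        values.append(float(v) if v is not None else np.nan)
        geoms.append(shape(feat["geometry"]))
    adj_pos = queen_adjacency(geoms)
    adjacency = {ids[i]: {ids[j] for j in nbrs} for i, nbrs in adj_pos.items()}
    return PolygonField(unit_ids=ids, adjacency=adjacency, values=values, geometry=geoms)


def read_polygon_csv(
    attributes_path,
    edges_path,
    value_field: str,
    id_field: str = "id",
) -> PolygonField:
    """Attribute table + two-column edge list -> PolygonField.

    The edge list is symmetrized; self-loops are rejected by the field
    constructor.  Missing or empty value cells become missing values.
    """
    ids, values = [], []
    with open(attributes_path, newline="") as fh:
        for row in csv.DictReader(fh):
            uid = _coerce_id(row[id_field])
            raw = row.get(value_field, "")
            ids.append(uid)
            values.append(float(raw) if raw not in ("", None, "NA", "nan") else np.nan)
    adjacency: dict = {u: set() for u in ids}
    with open(edges_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [header] if _looks_like_edge(header, adjacency) else []
        rows.extend(reader)
    for row in rows:
        if len(row) < 2 or not row[0].strip():
            continue
        a, b = _coerce_id(row[0]), _coerce_id(row[1])
        if a not in adjacency or b not in adjacency:
            raise GCCMError(f"edge ({a!r}, {b!r}) references unknown units")
        adjacency[a].add(b)
        adjacency[b].add(a)
    return PolygonField(unit_ids=ids, adjacency=adjacency, values=values)


def _coerce_id(token: str):
    token = token.strip()
    try:
        return int(token)
    except ValueError:
        return token


def _looks_like_edge(header: list[str], adjacency: dict) -> bool:
    return len(header) >= 2 and _coerce_id(header[0]) in adjacency


def write_results_csv(assessment, path) -> None:
    """direction, lib_size, rho, p, ci_low, ci_high, n — both curves stacked."""
    assessment.to_frame().to_csv(path, index=False)


def write_verdict_json(assessment, path, extra: dict | None = None) -> None:
    payload = {
        "verdict": assessment.verdict,
        "leading_direction": assessment.leading_direction,
        "notes": assessment.notes,
        "final": {
            s.direction: {"rho": s.rho, "p": s.p, "n": s.n,
                          "ci": [s.ci_low, s.ci_high]}
            for s in (assessment.curve_y_xmap_x[-1], assessment.curve_x_xmap_y[-1])
        },
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plot_convergence(assessment, path=None, ax=None):
    """Skill vs library size for both directions, with CI ribbons."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for curve, color in (
        (assessment.curve_y_xmap_x, "tab:blue"),
        (assessment.curve_x_xmap_y, "tab:orange"),
    ):
        sizes = [s.library_size for s in curve]
        rhos = [s.rho for s in curve]
        lo = [s.ci_low for s in curve]
        hi = [s.ci_high for s in curve]
        ax.plot(sizes, rhos, "-o", color=color, label=curve[0].direction)
        ax.fill_between(sizes, lo, hi, color=color, alpha=0.2)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("library size")
    ax.set_ylabel(r"cross-map skill $\rho$")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
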