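"""Segmented-cell table and ROI input/output.

The interchange format between upstream image segmentation (CellProfiler /
HORIZON-style exports) and the spatial analysis is a delimited text table
with one row per segmented cell: a cell id, an ROI id, (x, y) centroid
coordinates, and one column per marker holding the mean intensity of that
marker within the cell mask.

Conventions enforced here and assumed everywhere downstream:

* image coordinate convention — origin at the top-left, x rightward,
  y downward, 0-based;
* coordinates are stored in micrometers after ingestion.  The pixel scale
  is a **required** user input (segmentation exports are in pixels and do
  not record it); nothing is silently assumed;
* marker intensities are non-negative reals; cell ids are unique within
  an ROI.

Downstream distance math is purely Euclidean, so the axis convention never
matters beyond consistency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .errors import ConfigurationError, ParseError, SchemaError

#: Column names reserved for the canonical cell-table layout; every other
#: column of a cell table is treated as a marker-intensity column.
RESERVED_COLUMNS = ("cell_id", "roi_id", "x_um", "y_um", "phenotype", "lipid_positive")

#: Allowed region classes for an ROI.
REGION_CLASSES = ("TRPC", "TSC", "treated", "control", "other")


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

@dataclass
class ROIGeometry:
    """A region of interest: geometry plus region-class annotation.

    Exactly one of ``bounds`` (axis-aligned rectangle), ``polygon``
    (simple closed ring) or ``circle`` must be given.

    Parameters
    ----------
    roi_id : str
        Identifier, matching the ``roi_id`` column of cell tables.
    bounds : tuple, optional
        ``(xmin, ymin, xmax, ymax)`` in micrometers.
    polygon : sequence of (x, y), optional
        Vertices of a simple closed polygon in micrometers.  The ring may
        be given open (first vertex not repeated); it is closed here.
    circle : tuple, optional
        ``(cx, cy, radius)`` in micrometers.
    region_class : str
        One of ``TRPC, TSC, treated, control, other``.
    pixel_size_um : float
        Micrometers per pixel of the source image (> 0).  Recorded for
        provenance; geometry here is already in micrometers.
    """

    roi_id: str
    bounds: tuple[float, float, float, float] | None = None
    polygon: Sequence[tuple[float, float]] | None = None
    circle: tuple[float, float, float] | None = None
    region_class: str = "other"
    pixel_size_um: float = 1.0
    _poly: Polygon | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        given = [g is not None for g in (self.bounds, self.polygon, self.circle)]
        if sum(given) != 1:
            raise ConfigurationError(
                f"ROI {self.roi_id!r}: exactly one of bounds, polygon or circle "
                f"must be given ({sum(given)} given)"
            )
        if self.region_class not in REGION_CLASSES:
            raise ConfigurationError(
                f"ROI {self.roi_id!r}: region_class {self.region_class!r} not one "
                f"of {REGION_CLASSES}"
            )
        if not self.pixel_size_um > 0:
            raise ConfigurationError(
                f"ROI {self.roi_id!r}: pixel_size_um must be > 0"
            )
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            if not (xmax > xmin and ymax > ymin):
                raise ConfigurationError(
                    f"ROI {self.roi_id!r}: bounds must satisfy xmax>xmin, ymax>ymin"
                )
        if self.circle is not None:
            if not self.circle[2] > 0:
                raise ConfigurationError(f"ROI {self.roi_id!r}: circle radius must be > 0")
        if self.polygon is not None:
            ring = list(self.polygon)
            if len(ring) >= 2 and tuple(ring[0]) == tuple(ring[-1]):
                ring = ring[:-1]
            if len(ring) < 3:
                raise ConfigurationError(f"ROI {self.roi_id!r}: polygon needs >= 3 vertices")
            poly = Polygon(ring)
            if not poly.is_valid or not poly.is_simple:
                raise ConfigurationError(f"ROI {self.roi_id!r}: polygon must be simple")
            object.__setattr__(self, "_poly", poly)

    # -- geometry queries ---------------------------------------------------

    @property
    def area(self) -> float:
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            return (xmax - xmin) * (ymax - ymin)
        if self.circle is not None:
            return math.pi * self.circle[2] ** 2
        return self._poly.area

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """Axis-aligned bounding box ``(xmin, ymin, xmax, ymax)``."""
        if self.bounds is not None:
            return self.bounds
        if self.circle is not None:
            cx, cy, r = self.circle
            return (cx - r, cy - r, cx + r, cy + r)
        return self._poly.bounds

    def contains(self, x, y):
        """Vectorized point-in-region test (boundary counts as inside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        if self.circle is not None:
            cx, cy, r = self.circle
            return (x - cx) ** 2 + (y - cy) ** 2 <= r * r
        return shapely.intersects_xy(self._poly, x, y)

    def signed_boundary_distance(self, x, y):
        """Distance to the region boundary: positive inside, negative outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.bounds is not None:
            xmin, ymin, xmax, ymax = self.bounds
            dx = np.minimum(x - xmin, xmax - x)
            dy = np.minimum(y - ymin, ymax - y)
            inside = (dx >= 0) & (dy >= 0)
            inner = np.minimum(dx, dy)
            # outside a rectangle: Euclidean distance to the nearest edge point
            ox = np.maximum(np.maximum(xmin - x, x - xmax), 0.0)
            oy = np.maximum(np.maximum(ymin - y, y - ymax), 0.0)
            outer = np.hypot(ox, oy)
            return np.where(inside, inner, -outer)
        if self.circle is not None:
            cx, cy, r = self.circle
            return r - np.hypot(x - cx, y - cy)
        pts = shapely.points(x, y)
        d = shapely.distance(self._poly.exterior, pts)
        inside = shapely.intersects_xy(self._poly, x, y)
        return np.where(inside, d, -d)


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

def validate_cell_table(cells: pd.DataFrame) -> None:
    """Check the canonical cell-table invariants, raising :class:`SchemaError`.

    Required columns: ``cell_id, roi_id, x_um, y_um``.  Coordinates must be
    finite and non-negative; marker columns non-negative; ``cell_id`` unique
    within each ROI.
    """
    missing = [c for c in ("cell_id", "roi_id", "x_um", "y_um") if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing mandatory column(s): {missing}")
    for c in ("x_um", "y_um"):
        v = cells[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            bad = cells.index[~np.isfinite(v)].tolist()[:10]
            raise SchemaError(f"non-finite {c} at row index(es) {bad}")
        if np.any(v < 0):
            bad = cells.index[v < 0].tolist()[:10]
            raise SchemaError(f"negative {c} at row index(es) {bad}")
    dup = cells.duplicated(subset=["roi_id", "cell_id"], keep=False)
    if dup.any():
        dup_ids = cells.loc[dup, ["roi_id", "cell_id"]].drop_duplicates()
        raise SchemaError(
            "duplicated cell_id within an ROI: "
            + "; ".join(f"{r.roi_id}/{r.cell_id}" for r in dup_ids.itertuples())
        )
    for c in marker_columns(cells):
        v = pd.to_numeric(cells[c], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(v)) or np.any(v < 0):
            raise SchemaError(f"marker column {c!r} must be non-negative numeric")


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Columns of ``cells`` holding marker intensities (all non-reserved)."""
    return [c for c in cells.columns if c not in RESERVED_COLUMNS]


def read_cell_table(
    path,
    schema: Mapping[str, object],
    pixel_size_um: float,
    *,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a segmented-cell table and convert it to the canonical layout.

    Parameters
    ----------
    path : path-like
        Comma- or tab-delimited text file with a header row.  The dialect
        is sniffed unless ``delimiter`` is given.
    schema : mapping
        Column-name map: must provide ``cell_id``, ``x`` and ``y``;
        may provide ``roi_id`` and ``intensities`` (either a list of
        column names or a ``{marker: column}`` map).  When ``intensities``
        is omitted every unmapped column is taken as a marker, keyed by
        its header.
    pixel_size_um : float
        Micrometers per pixel; coordinates are multiplied by this factor.
        Pass 1.0 when the export is already in micrometers.

    Returns
    -------
    pandas.DataFrame
        Canonical cell table: ``cell_id, roi_id, x_um, y_um`` plus one
        column per marker, in the input row order.

    Raises
    ------
    SchemaError
        A mandatory column is missing, or a cell id repeats within an ROI.
    ParseError
        A coordinate or intensity cell is non-numeric, negative or
        non-finite; the message names the file line numbers (1-based,
        counting the header as line 1).
    """
    if not pixel_size_um > 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    for key in ("cell_id", "x", "y"):
        if key not in schema:
            raise SchemaError(f"schema must map {key!r} to a column name")
    if delimiter is None:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)

    def _col(key):
        name = schema[key]
        if name not in raw.columns:
            raise SchemaError(f"column {name!r} (schema role {key!r}) not in file header")
        return name

    id_col, x_col, y_col = _col("cell_id"), _col("x"), _col("y")
    roi_col = _col("roi_id") if "roi_id" in schema else None

    def _numeric(colname, role, allow_negative=False):
        v = pd.to_numeric(raw[colname], errors="coerce")
        bad = v.isna() | ~np.isfinite(v.fillna(0.0))
        if not allow_negative:
            bad |= v < 0
        if bad.any():
            lines = (raw.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
            raise ParseError(
                f"column {colname!r} ({role}): non-numeric/negative value(s) at "
                f"file line(s) {lines}"
            )
        return v.to_numpy(dtype=float)

    x = _numeric(x_col, "x coordinate")
    y = _numeric(y_col, "y coordinate")

    out = pd.DataFrame(
        {
            "cell_id": raw[id_col].astype(str),
            "roi_id": raw[roi_col].astype(str) if roi_col else "roi_0",
            "x_um": x * pixel_size_um,
            "y_um": y * pixel_size_um,
        }
    )

    spec = schema.get("intensities")
    if spec is None:
        used = {id_col, x_col, y_col} | ({roi_col} if roi_col else set())
        pairs = [(c, c) for c in raw.columns if c not in used]
    elif isinstance(spec, Mapping):
        pairs = [(m, c) for m, c in spec.items()]
    else:
        pairs = [(c, c) for c in spec]
    for marker, colname in pairs:
        if colname not in raw.columns:
            raise SchemaError(f"intensity column {colname!r} not in file header")
        out[marker] = _numeric(colname, f"marker {marker!r}")

    validate_cell_table(out)
    return out


def read_roi_table(path, polygon_path=None) -> dict[str, ROIGeometry]:
    """Read ROI metadata from a CSV.

    Expected columns: ``roi_id, region_class`` plus either rectangle bounds
    ``xmin, ymin, xmax, ymax`` or circle ``cx, cy, radius``; optional
    ``pixel_size_um``.  ROIs whose geometry columns are all empty must
    appear in ``polygon_path`` (CSV with columns ``roi_id, x, y``, vertices
    in ring order).
    """
    meta = pd.read_csv(path)
    if "roi_id" not in meta.columns:
        raise SchemaError("ROI table must have a roi_id column")
    polys: dict[str, list[tuple[float, float]]] = {}
    if polygon_path is not None:
        pv = pd.read_csv(polygon_path)
        for rid, grp in pv.groupby("roi_id", sort=False):
            polys[str(rid)] = list(zip(grp["x"].astype(float), grp["y"].astype(float)))
    rois: dict[str, ROIGeometry] = {}
    for row in meta.itertuples(index=False):
        d = row._asdict()
        rid = str(d["roi_id"])
        kw = dict(
            roi_id=rid,
            region_class=str(d.get("region_class", "other")),
            pixel_size_um=float(d.get("pixel_size_um", 1.0) or 1.0),
        )
        if all(k in d and pd.notna(d[k]) for k in ("xmin", "ymin", "xmax", "ymax")):
            kw["bounds"] = tuple(float(d[k]) for k in ("xmin", "ymin", "xmax", "ymax"))
        elif all(k in d and pd.notna(d[k]) for k in ("cx", "cy", "radius")):
            kw["circle"] = tuple(float(d[k]) for k in ("cx", "cy", "radius"))
        elif rid in polys:
            kw["polygon"] = polys[rid]
        else:
            raise SchemaError(f"ROI {rid!r}: no geometry columns and no polygon entry")
        rois[rid] = ROIGeometry(**kw)
    return rois


def assert_cells_in_roi(cells: pd.DataFrame, roi: ROIGeometry) -> None:
    """Raise :class:`SchemaError` if any cell assigned to ``roi`` lies outside it."""
    sub = cells[cells["roi_id"] == roi.roi_id]
    if len(sub) == 0:
        return
    inside = roi.contains(sub["x_um"].to_numpy(), sub["y_um"].to_numpy())
    if not np.all(inside):
        bad = sub.loc[~inside, "cell_id"].tolist()[:10]
        raise SchemaError(f"cell(s) {bad} assigned to ROI {roi.roi_id!r} lie outside it")


# ---------------------------------------------------------------------------
# Summary I/O
# ---------------------------------------------------------------------------

def write_summary(summary: pd.DataFrame, path, format: str = "delimited") -> None:
    """Write a summary table so that :func:`read_summary` round-trips it.

    ``delimited`` writes CSV (floats in shortest round-trip repr);
    ``structured`` writes a human-readable key-value block per row.
    """
    summary = pd.DataFrame(summary)
    if format == "delimited":
        summary.to_csv(path, index=False)
    elif format == "structured":
        with open(path, "w") as fh:
            fh.write("# cellhood summary v1\n")
            fh.write(f"# columns: {', '.join(map(str, summary.columns))}\n")
            for i, (_, row) in enumerate(summary.iterrows()):
                fh.write(f"[{i}]\n")
                for col in summary.columns:
                    val = row[col]
                    if hasattr(val, "item"):
                        val = val.item()
                    fh.write(f"{col} = {val!r}\n")
    else:
        raise ConfigurationError(f"unknown summary format {format!r}")


def read_summary(path, format: str | None = None) -> pd.DataFrame:
    """Read a summary written by :func:`write_summary` (format auto-detected)."""
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "structured" if first.startswith("# cellhood summary") else "delimited"
    if format == "delimited":
        return pd.read_csv(path, float_precision="round_trip")
    rows: list[dict] = []
    current: dict | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                if current is not None:
                    rows.append(current)
                current = {}
                continue
            key, _, val = line.partition(" = ")
            current[key] = _parse_scalar(val)
    if current is not None:
        rows.append(current)
    return pd.DataFrame(rows)


def _parse_scalar(text: str):
    if text.startswith(("'", '"')) and text.endswith(("'", '"')):
        return text[1:-1]
    if text == "True":
        return True
    if text == "False":
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text
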