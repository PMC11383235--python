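"""Reading and writing per-nucleus detection tables.

Detection tables are delimited text exports from a segmentation tool
(one row per detected nucleus), carrying the centroid position, the
nucleus area and per-nucleus median stain values.  Internally all
coordinates and areas are expressed in microns; a :class:`TableDialect`
maps arbitrary export schemas (column names, delimiter, coordinate
units) onto that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusRecord",
    "DetectionSet",
    "TableDialect",
    "QUPATH_DIALECT",
    "FormatError",
    "read_detections",
    "write_detections",
    "px_to_um",
]


class FormatError(ValueError):
    """A detection table does not conform to the declared dialect."""


@dataclass(frozen=True)
class NucleusRecord:
    """One detected nucleus.

    Attributes
    ----------
    id:
        Opaque identifier, unique within its :class:`DetectionSet`.
    x_um, y_um:
        Centroid coordinates in microns, image convention (origin
        top-left, y increasing downward), slide frame.
    area_um2:
        Nucleus area in square microns; strictly positive.
    hema_median, eosin_median:
        Median per-pixel hematoxylin / eosin values of the nucleus
        (dimensionless optical values).
    """

    id: str
    x_um: float
    y_um: float
    area_um2: float
    hema_median: float
    eosin_median: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError(f"nucleus {self.id!r}: non-finite centroid")
        if not self.area_um2 > 0:
            raise ValueError(f"nucleus {self.id!r}: area must be > 0, got {self.area_um2}")


@dataclass
class DetectionSet:
    """All nuclei detected in one scan replicate within one ROI.

    ``roi_bounds`` is the axis-aligned ROI rectangle
    ``(x_min, y_min, x_max, y_max)`` in microns; bounds are inclusive,
    so a record exactly on an edge is inside.
    """

    scan_id: str
    roi_id: str
    records: list[NucleusRecord]
    roi_bounds: tuple[float, float, float, float]
    pixel_size_um: float

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.roi_bounds
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate ROI bounds {self.roi_bounds}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate nucleus ids within DetectionSet")
        for r in self.records:
            if not (x0 <= r.x_um <= x1 and y0 <= r.y_um <= y1):
                raise ValueError(
                    f"nucleus {r.id!r} at ({r.x_um}, {r.y_um}) outside ROI bounds {self.roi_bounds}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NucleusRecord]:
        return iter(self.records)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of centroid coordinates in microns."""
        return np.array([[r.x_um, r.y_um] for r in self.records], dtype=float).reshape(-1, 2)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def feature(self, name: str) -> np.ndarray:
        """Per-nucleus values of ``area_um2``, ``hema_median`` or ``eosin_median``."""
        if name not in ("area_um2", "hema_median", "eosin_median"):
            raise KeyError(name)
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    def by_id(self) -> dict[str, NucleusRecord]:
        return {r.id: r for r in self.records}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "x_um": [r.x_um for r in self.records],
                "y_um": [r.y_um for r in self.records],
                "area_um2": [r.area_um2 for r in self.records],
                "hema_median": [r.hema_median for r in self.records],
                "eosin_median": [r.eosin_median for r in self.records],
            }
        )

    def translated(self, dx: float, dy: float, expand_bounds: bool = True) -> "DetectionSet":
        """Copy with all centroids (and bounds) shifted by ``(dx, dy)`` microns."""
        recs = [replace(r, x_um=r.x_um + dx, y_um=r.y_um + dy) for r in self.records]
        x0, y0, x1, y1 = self.roi_bounds
        return DetectionSet(
            scan_id=self.scan_id,
            roi_id=self.roi_id,
            records=recs,
            roi_bounds=(x0 + dx, y0 + dy, x1 + dx, y1 + dy),
            pixel_size_um=self.pixel_size_um,
        )


@dataclass(frozen=True)
class TableDialect:
    """Maps a detection-table schema onto :class:`NucleusRecord` fields.

    ``coordinate_unit`` is ``"um"`` or ``"px"``; pixel coordinates are
    converted to microns on read using the set's pixel size.  ``id_column``
    of ``None`` means ids are generated sequentially (``"n0", "n1", ...``).
    Area in pixel units is converted with the squared pixel size.
    """

    delimiter: str = "\t"
    x_column: str = "Centroid X µm"
    y_column: str = "Centroid Y µm"
    area_column: str = "Nucleus: Area"
    hema_column: str = "Nucleus: Hematoxylin OD median"
    eosin_column: str = "Nucleus: Eosin OD median"
    id_column: str | None = None
    coordinate_unit: str = "um"
    area_unit: str = "um2"

    def __post_init__(self) -> None:
        if self.coordinate_unit not in ("um", "px"):
            raise ValueError(f"coordinate_unit must be 'um' or 'px', got {self.coordinate_unit!r}")
        if self.area_unit not in ("um2", "px2"):
            raise ValueError(f"area_unit must be 'um2' or 'px2', got {self.area_unit!r}")


#: Default dialect mimicking a QuPath measurement export.
QUPATH_DIALECT = TableDialect()

#: Dialect used by :func:`write_detections`: plain names, microns, TSV.
_CANONICAL_DIALECT = TableDialect(
    x_column="x_um",
    y_column="y_um",
    area_column="area_um2",
    hema_column="hema_median",
    eosin_column="eosin_median",
    id_column="id",
)


def px_to_um(length_px: float, pixel_size_um: float) -> float:
    """Convert a pixel length to microns (e.g. a 2000 px ROI side at
    0.11 μm/px is 220 μm)."""
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if not (np.isfinite(length_px) and np.isfinite(pixel_size_um)):
        raise ValueError("inputs must be finite")
    return length_px * pixel_size_um


def read_detections(
    path: str | Path,
    dialect: TableDialect = QUPATH_DIALECT,
    *,
    scan_id: str = "scan",
    roi_id: str = "roi",
    pixel_size_um: float = 0.11,
    roi_bounds: tuple[float, float, float, float] | None = None,
) -> DetectionSet:
    """Read a delimited detection table into a :class:`DetectionSet`.

    Coordinates are normalised to microns and row order is preserved.
    If ``roi_bounds`` is not given it is taken as the tight bounding box
    of the detections (padded marginally for a degenerate extent).
    An empty file (header only, or fully empty) yields an empty set.

    Raises
    ------
    FormatError
        If a mapped column is missing, or a coordinate/area value fails
        to parse (the error names the offending column and row).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()

    required = [dialect.x_column, dialect.y_column, dialect.area_column,
                dialect.hema_column, dialect.eosin_column]
    if dialect.id_column is not None:
        required.append(dialect.id_column)
    if len(df) > 0 or len(df.columns) > 0:
        for col in required:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")

    records: list[NucleusRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_map = dict(zip(df.columns, row))

        def _num(col: str) -> float:
            raw = row_map[col]
            try:
                return float(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {i}: non-numeric value {raw!r} in column {col!r}"
                ) from None

        x, y = _num(dialect.x_column), _num(dialect.y_column)
        area = _num(dialect.area_column)
        if dialect.coordinate_unit == "px":
            x, y = x * pixel_size_um, y * pixel_size_um
        if dialect.area_unit == "px2":
            area *= pixel_size_um**2
        rid = str(row_map[dialect.id_column]) if dialect.id_column is not None else f"n{i}"
        records.append(
            NucleusRecord(
                id=rid,
                x_um=x,
                y_um=y,
                area_um2=area,
                hema_median=_num(dialect.hema_column),
                eosin_median=_num(dialect.eosin_column),
            )
        )

    if roi_bounds is None:
        roi_bounds = _tight_bounds(records)
    return DetectionSet(
        scan_id=scan_id,
        roi_id=roi_id,
        records=records,
        roi_bounds=roi_bounds,
        pixel_size_um=pixel_size_um,
    )


def _tight_bounds(records: Sequence[NucleusRecord]) -> tuple[float, float, float, float]:
    if not records:
        return (0.0, 0.0, 1.0, 1.0)
    xs = [r.x_um for r in records]
    ys = [r.y_um for r in records]
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    # avoid a zero-width rectangle for single-point or collinear sets
    pad = 1e-6
    if x1 <= x0:
        x0, x1 = x0 - pad, x1 + pad
    if y1 <= y0:
        y0, y1 = y0 - pad, y1 + pad
    return (x0, y0, x1, y1)


def write_detections(ds: DetectionSet, path: str | Path) -> None:
    """Write a :class:`DetectionSet` as a tab-delimited micron-unit table.

    The output uses canonical column names (``id``, ``x_um``, ...) and
    ``repr``-precision floats, so ``read_detections`` with
    :data:`canonical_dialect` recovers the set losslessly.
    """
    df = ds.to_dataframe()
    df.to_csv(Path(path), sep="\t", index=False, float_format=None)


def canonical_dialect() -> TableDialect:
    """Dialect matching the output of :func:`write_detections`."""
    return _CANONICAL_DIALECT


def read_geojson_detections(
    path: str | Path,
    *,
    scan_id: str = "scan",
    roi_id: str = "roi",
    pixel_size_um: float = 0.11,
    roi_bounds: tuple[float, float, float, float] | None = None,
    measurement_keys: tuple[str, str, str] = ("area_um2", "hema_median", "eosin_median"),
) -> DetectionSet:
    """Read a GeoJSON FeatureCollection of detections (micron coordinates).

    Each feature contributes its geometry centroid (Point coordinates, or
    mean of polygon exterior vertices) and the named measurement
    properties.
    """
    import json

    with open(path) as fh:
        doc = json.load(fh)
    records = []
    a_key, h_key, e_key = measurement_keys
    for i, feat in enumerate(doc.get("features", [])):
        geom = feat["geometry"]
        if geom["type"] == "Point":
            x, y = geom["coordinates"][:2]
        elif geom["type"] == "Polygon":
            ring = np.asarray(geom["coordinates"][0], dtype=float)
            x, y = ring[:, 0].mean(), ring[:, 1].mean()
        else:
            raise FormatError(f"{path}: unsupported geometry type {geom['type']!r}")
        props = feat.get("properties", {})
        meas = props.get("measurements", props)
        records.append(
            NucleusRecord(
                id=str(props.get("id", f"n{i}")),
                x_um=float(x),
                y_um=float(y),
                area_um2=float(meas[a_key]),
                hema_median=float(meas[h_key]),
                eosin_median=float(meas[e_key]),
            )
        )
    if roi_bounds is None:
        roi_bounds = _tight_bounds(records)
    return DetectionSet(scan_id=scan_id, roi_id=roi_id, records=records,
                        roi_bounds=roi_bounds, pixel_size_um=pixel_size_um)
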