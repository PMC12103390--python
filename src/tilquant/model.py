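"""Cell-table data model, region geometry and on-disk formats.

The pipeline operates on segmented-cell tables from multiplexed
immunohistochemistry (mIHC): one row per cell with 2-D coordinates in
micrometres, binary positivity calls (optionally raw intensities) for the
six-marker panel PANCK / CD4 / CD8 / LAG3 / KI67 / IFNG, and a region label
(tumor, stroma or excluded).  Coordinates are continuous micrometres with the
origin at the lower-left corner of the analyzable window; all areas are
reported in mm^2 (1 mm^2 = 1e6 um^2) because cell densities are conventionally
quoted per mm^2.

On-disk formats
---------------
Cell table
    UTF-8 CSV with header ``cell_id,x_um,y_um,PANCK,CD4,CD8,LAG3,KI67,IFNG``
    plus optional ``<marker>_intensity`` columns and an optional ``region``
    column.  Floats are written at full precision so tables round-trip
    exactly.
Region masks
    GeoJSON Polygon / MultiPolygon geometries with coordinates in um.
Clinical table
    CSV with ``patient_id,os_months,event`` (optional ``timepoint``).
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape
from shapely.ops import unary_union

#: Default marker panel, in canonical column order.
PANEL: tuple[str, ...] = ("PANCK", "CD4", "CD8", "LAG3", "KI67", "IFNG")

#: Valid region labels for a cell.
REGIONS: tuple[str, ...] = ("tumor", "stroma", "excluded")

#: Valid sampling timepoints relative to chemoradiotherapy.
TIMEPOINTS: tuple[str, ...] = ("baseline", "on_treatment", "post_treatment")

UM2_PER_MM2 = 1.0e6


class TilquantError(Exception):
    """Base class for all package errors."""


class FormatError(TilquantError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(TilquantError):
    """Data violates a model invariant (bad coordinate, bad label, bad ring)."""


class ConfigError(TilquantError):
    """A rule, threshold or generator configuration is inconsistent."""


class InsufficientDataError(TilquantError):
    """Too few usable observations for the requested statistic."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """A single segmented cell.

    ``markers`` maps every panel marker to a 0/1 positivity call;
    ``intensities`` optionally carries raw staining intensities (arbitrary
    units, >= 0) used only by threshold-based positivity calling.
    """

    cell_id: str
    x: float
    y: float
    markers: Mapping[str, int]
    region: str = "stroma"
    intensities: Mapping[str, float] | None = None


@dataclass
class SurvivalRecord:
    """Overall survival for one patient: follow-up in months + event flag."""

    patient_id: str
    os_months: float
    event: int

    def validate(self) -> None:
        if not math.isfinite(self.os_months) or self.os_months < 0:
            raise ValidationError(
                f"patient {self.patient_id!r}: os_months must be finite and >= 0, "
                f"got {self.os_months}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"patient {self.patient_id!r}: event must be 0 or 1, got {self.event}"
            )


class RegionGeometry:
    """Tumor / exclusion polygons plus the rectangular analyzable window.

    Areas are derived quantities: overlapping tumor polygons are unioned,
    everything is clipped to the window, exclusions take precedence over
    tumor, and the stroma is whatever remains, so that::

        tumor_area + stroma_area + exclusion_area == window_area
    """

    def __init__(
        self,
        window: tuple[float, float, float, float],
        tumor_polygons: Sequence[Polygon] = (),
        exclusion_polygons: Sequence[Polygon] = (),
    ) -> None:
        minx, miny, maxx, maxy = (float(v) for v in window)
        if not all(math.isfinite(v) for v in (minx, miny, maxx, maxy)):
            raise ValidationError("window bounds must be finite")
        if maxx <= minx or maxy <= miny:
            raise ValidationError(f"degenerate window {window}")
        self.window = (minx, miny, maxx, maxy)
        self.tumor_polygons = list(tumor_polygons)
        self.exclusion_polygons = list(exclusion_polygons)
        self._window_box = box(minx, miny, maxx, maxy)
        excl = unary_union(self.exclusion_polygons) if self.exclusion_polygons else None
        tum = unary_union(self.tumor_polygons) if self.tumor_polygons else None
        self._excl_union = (
            excl.intersection(self._window_box) if excl is not None else None
        )
        if tum is not None:
            tum = tum.intersection(self._window_box)
            if self._excl_union is not None:
                tum = tum.difference(self._excl_union)
        self._tumor_union = tum

    @property
    def window_area_mm2(self) -> float:
        return self._window_box.area / UM2_PER_MM2

    @property
    def tumor_area_mm2(self) -> float:
        return (self._tumor_union.area if self._tumor_union is not None else 0.0) / UM2_PER_MM2

    @property
    def exclusion_area_mm2(self) -> float:
        return (self._excl_union.area if self._excl_union is not None else 0.0) / UM2_PER_MM2

    @property
    def stroma_area_mm2(self) -> float:
        return self.window_area_mm2 - self.tumor_area_mm2 - self.exclusion_area_mm2

    def area_mm2(self, region: str) -> float:
        """Area of ``tumor``, ``stroma`` or ``all`` (tumor + stroma) in mm^2."""
        if region == "tumor":
            return self.tumor_area_mm2
        if region == "stroma":
            return self.stroma_area_mm2
        if region == "all":
            return self.tumor_area_mm2 + self.stroma_area_mm2
        raise ValueError(f"unknown region {region!r}")

    def label_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region label per point; exclusion takes precedence over tumor.

        Points exactly on a polygon boundary count as inside (closed
        polygons).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        labels = np.full(x.shape, "stroma", dtype=object)
        if self._tumor_union is not None and not self._tumor_union.is_empty:
            labels[shapely.intersects_xy(self._tumor_union, x, y)] = "tumor"
        if self._excl_union is not None and not self._excl_union.is_empty:
            labels[shapely.intersects_xy(self._excl_union, x, y)] = "excluded"
        return labels


@dataclass
class TissueSample:
    """All cells of one section plus its region geometry and metadata.

    ``cells`` is a DataFrame with columns ``cell_id, x_um, y_um``, one 0/1
    column per panel marker, optional ``<marker>_intensity`` columns and a
    ``region`` column (one of tumor/stroma/excluded).
    """

    patient_id: str
    timepoint: str
    cells: pd.DataFrame
    geometry: RegionGeometry
    panel: tuple[str, ...] = PANEL

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def intensity_markers(self) -> tuple[str, ...]:
        return tuple(
            m for m in self.panel if f"{m}_intensity" in self.cells.columns
        )

    def iter_cells(self) -> Iterator[Cell]:
        imark = self.intensity_markers
        for row in self.cells.itertuples(index=False):
            d = row._asdict()
            yield Cell(
                cell_id=d["cell_id"],
                x=d["x_um"],
                y=d["y_um"],
                markers={m: int(d[m]) for m in self.panel},
                region=d["region"],
                intensities=(
                    {m: float(d[f"{m}_intensity"]) for m in imark} if imark else None
                ),
            )

    def validate(self) -> None:
        """Check every model invariant; raise ``ValidationError`` on failure."""
        df = self.cells
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        for col in ("cell_id", "x_um", "y_um", "region", *self.panel):
            if col not in df.columns:
                raise ValidationError(f"cells table lacks column {col!r}")
        if df["cell_id"].duplicated().any():
            dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValidationError(f"duplicate cell_id {dup!r}")
        xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
        bad = ~np.isfinite(xy).all(axis=1)
        if bad.any():
            cid = df.loc[bad, "cell_id"].iloc[0]
            raise ValidationError(f"cell {cid!r} has non-finite coordinates")
        minx, miny, maxx, maxy = self.geometry.window
        if len(df) and (
            (xy[:, 0] < minx).any()
            or (xy[:, 0] > maxx).any()
            or (xy[:, 1] < miny).any()
            or (xy[:, 1] > maxy).any()
        ):
            out = ~(
                (xy[:, 0] >= minx)
                & (xy[:, 0] <= maxx)
                & (xy[:, 1] >= miny)
                & (xy[:, 1] <= maxy)
            )
            cid = df.loc[out, "cell_id"].iloc[0]
            raise ValidationError(f"cell {cid!r} lies outside the window")
        if not df["region"].isin(REGIONS).all():
            bad_lab = df.loc[~df["region"].isin(REGIONS), "region"].iloc[0]
            raise ValidationError(f"unknown region label {bad_lab!r}")
        for m in self.panel:
            vals = df[m].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError(f"marker {m} has non-binary positivity values")

    def copy(self) -> "TissueSample":
        return TissueSample(
            patient_id=self.patient_id,
            timepoint=self.timepoint,
            cells=self.cells.copy(),
            geometry=self.geometry,
            panel=self.panel,
        )


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

def _default_geometry(df: pd.DataFrame) -> RegionGeometry:
    """Tight bounding window anchored at the origin (no region polygons)."""
    if len(df):
        maxx = float(df["x_um"].max())
        maxy = float(df["y_um"].max())
    else:
        maxx = maxy = 1.0
    return RegionGeometry(window=(0.0, 0.0, max(maxx, 1e-9), max(maxy, 1e-9)))


def read_cell_table(
    path: str | Path,
    panel: Sequence[str] = PANEL,
    *,
    patient_id: str | None = None,
    timepoint: str = "baseline",
    geometry: RegionGeometry | None = None,
) -> TissueSample:
    """Read a cell-table CSV into a validated :class:`TissueSample`.

    Intensity columns (``<marker>_intensity``) are preserved untouched;
    thresholding is a separate operation.  A missing required column raises
    :class:`FormatError`; a non-finite coordinate raises
    :class:`ValidationError` naming the offending ``cell_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str})
    required = ["cell_id", "x_um", "y_um", *panel]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    for col in ("x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    xy = df[["x_um", "y_um"]].to_numpy(dtype=float)
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        cid = df.loc[bad, "cell_id"].iloc[0]
        raise ValidationError(f"{path.name}: cell {cid!r} has missing/non-finite coordinates")
    for m in panel:
        vals = pd.to_numeric(df[m], errors="coerce").to_numpy()
        if not np.isin(vals[np.isfinite(vals)], (0, 1)).all() or not np.isfinite(vals).all():
            raise ValidationError(f"{path.name}: marker column {m} must contain only 0/1")
        df[m] = vals.astype(np.int8)
    if "region" not in df.columns:
        df["region"] = "stroma"
    icols = [c for c in df.columns if c.endswith("_intensity")]
    keep = ["cell_id", "x_um", "y_um", *panel, *icols, "region"]
    df = df[keep].reset_index(drop=True)
    sample = TissueSample(
        patient_id=patient_id if patient_id is not None else path.stem,
        timepoint=timepoint,
        cells=df,
        geometry=geometry if geometry is not None else _default_geometry(df),
        panel=tuple(panel),
    )
    sample.validate()
    return sample


def write_cell_table(sample: TissueSample, path: str | Path) -> None:
    """Write a sample as the CSV dialect accepted by :func:`read_cell_table`."""
    icols = [c for c in sample.cells.columns if c.endswith("_intensity")]
    cols = ["cell_id", "x_um", "y_um", *sample.panel, *icols, "region"]
    sample.cells[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Polygon (GeoJSON) I/O
# ---------------------------------------------------------------------------

def _validate_ring(coords: Sequence[Sequence[float]], idx: int) -> None:
    pts = [tuple(map(float, p)) for p in coords]
    if pts and pts[0] == pts[-1]:
        pts = pts[:-1]
    if len(set(pts)) < 3:
        raise ValidationError(f"ring {idx}: fewer than 3 distinct vertices")


def _polygons_from_geometry(geom: dict, polygons: list[Polygon]) -> None:
    gtype = geom.get("type")
    if gtype == "Polygon":
        rings = geom["coordinates"]
        for idx, ring in enumerate(rings):
            _validate_ring(ring, idx=len(polygons) if idx == 0 else idx)
        poly = shape(geom)
        if not poly.is_valid:
            raise ValidationError(
                f"ring {len(polygons)}: self-intersecting or otherwise invalid polygon"
            )
        polygons.append(poly)
    elif gtype == "MultiPolygon":
        for coords in geom["coordinates"]:
            _polygons_from_geometry({"type": "Polygon", "coordinates": coords}, polygons)
    elif gtype in ("Feature",):
        _polygons_from_geometry(geom["geometry"], polygons)
    elif gtype in ("FeatureCollection",):
        for feat in geom["features"]:
            _polygons_from_geometry(feat, polygons)
    elif gtype == "GeometryCollection":
        for g in geom["geometries"]:
            _polygons_from_geometry(g, polygons)
    else:
        raise FormatError(f"unsupported GeoJSON geometry type {gtype!r}")


def read_polygons(path: str | Path) -> list[Polygon]:
    """Read GeoJSON polygon masks (coordinates in um).

    Degenerate rings (< 3 distinct vertices) and self-intersecting rings are
    rejected with a :class:`ValidationError` naming the ring index.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    polygons: list[Polygon] = []
    _polygons_from_geometry(doc, polygons)
    return polygons


def write_polygons(polygons: Sequence[Polygon], path: str | Path) -> None:
    """Write polygons as a GeoJSON MultiPolygon document."""
    geom = mapping(MultiPolygon([Polygon(p.exterior, p.interiors) for p in polygons]))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(geom, fh)


def polygon_area_mm2(polygon: Polygon) -> float:
    """Area of a polygon whose coordinates are in um, reported in mm^2."""
    return polygon.area / UM2_PER_MM2


# ---------------------------------------------------------------------------
# Clinical-table I/O
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    """Read ``patient_id,os_months,event`` CSV into survival records."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "os_months", "event"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        rec = SurvivalRecord(
            patient_id=row.patient_id,
            os_months=float(row.os_months),
            event=int(row.event),
        )
        rec.validate()
        records.append(rec)
    return records


def write_clinical(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "os_months": [r.os_months for r in records],
            "event": [r.event for r in records],
        }
    ).to_csv(path, index=False)
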