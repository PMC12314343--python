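"""Core data model and table I/O for segmented-object sections.

A *section* is a 2D tissue slice represented as a collection of segmented
objects (cells, vessel/tumour pseudo-cells, in-situ probe surfaces), each
reduced to its centroid in µm, a volume and optional channel intensities.
Tables follow the statistics-export convention of common segmentation
software: one CSV per object class with ``Position X`` / ``Position Y``
(optionally ``Position Z``) coordinate columns, and a folder per sample
holding one such CSV per class.

Analysis is strictly planar: a Z coordinate is read if present but never
used downstream (sections are thin relative to lateral extent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.prepared import prep

__all__ = [
    "OBJECT_CLASSES",
    "SegmentedObject",
    "SectionDataset",
    "TableFormatError",
    "read_objects_table",
    "write_objects_table",
    "load_sample_folder",
    "tile_region_to_pseudocells",
    "DEFAULT_CLASS_FILE_MAP",
]

#: Recognised object classes. ``vessel`` and ``tumour`` rows are pseudo-cells
#: obtained by tiling extended structures; ``probe_*`` rows are in-situ
#: hybridisation probe surfaces (transcript puncta).
OBJECT_CLASSES = (
    "cDC1",
    "CD8T",
    "CD4T",
    "vessel",
    "tumour",
    "probe_Cxcl9",
    "probe_Il12b",
)

#: Default mapping from lower-case file stem to object class for
#: folder-per-sample loading. Override via ``class_file_map``.
DEFAULT_CLASS_FILE_MAP: dict[str, str] = {
    "cdc1": "cDC1",
    "cd8": "CD8T",
    "cd8t": "CD8T",
    "cd4": "CD4T",
    "cd4t": "CD4T",
    "vessel": "vessel",
    "vessels": "vessel",
    "tumour": "tumour",
    "tumor": "tumour",
    "probe_cxcl9": "probe_Cxcl9",
    "probe_il12b": "probe_Il12b",
}

# Column aliases resolved case-insensitively when reading tables.
_X_ALIASES = ("position x", "x", "position_x", "pos_x", "centroid_x")
_Y_ALIASES = ("position y", "y", "position_y", "pos_y", "centroid_y")
_Z_ALIASES = ("position z", "z", "position_z", "pos_z", "centroid_z")
_VOL_ALIASES = ("volume", "vol")
_ID_ALIASES = ("id", "object_id", "surface_id")


class TableFormatError(ValueError):
    """Raised when an object table violates the expected CSV contract."""


@dataclass
class SegmentedObject:
    """One segmented object: a cell, pseudo-cell or probe surface.

    Coordinates are centroids in µm. ``volume`` is in µm³ (an area times a
    unit depth for pseudo-cells tiled from 2D masks). ``labels`` carries
    categorical annotations such as ``state`` ("Cxcl9" | "Il12b" | "none")
    or ``tcf1`` ("pos" | "neg").
    """

    id: int
    object_class: str
    x: float
    y: float
    z: float | None = None
    volume: float = 0.0
    intensities: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.object_class not in OBJECT_CLASSES:
            raise ValueError(f"unknown object class {self.object_class!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for object {self.id}")
        if self.volume < 0:
            raise ValueError(f"negative volume for object {self.id}")

    @property
    def effective_radius(self) -> float:
        """Disc-equivalent radius (µm) from volume at unit depth."""
        return math.sqrt(self.volume / math.pi) if self.volume > 0 else 0.0


@dataclass
class SectionDataset:
    """All segmented objects of one tissue section plus its bounding box."""

    section_id: str
    objects: list[SegmentedObject]
    bbox: tuple[float, float, float, float]
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.bbox
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"bbox {self.bbox} has non-positive area")
        ids = [o.id for o in self.objects]
        if len(ids) != len(set(ids)):
            raise ValueError("object ids are not unique within the section")

    def of_class(self, object_class: str) -> list[SegmentedObject]:
        return [o for o in self.objects if o.object_class == object_class]

    def coords(self, object_class: str | None = None) -> np.ndarray:
        objs = self.objects if object_class is None else self.of_class(object_class)
        if not objs:
            return np.empty((0, 2), dtype=float)
        return np.array([(o.x, o.y) for o in objs], dtype=float)

    @property
    def classes(self) -> list[str]:
        return sorted({o.object_class for o in self.objects})


def _resolve_column(columns: Sequence[str], aliases: Sequence[str]) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    return None


def read_objects_table(path: str | Path, object_class: str) -> list[SegmentedObject]:
    """Read one per-class CSV of segmented objects.

    Required columns: ``Position X`` and ``Position Y`` (aliases ``x``/``y``
    accepted, case-insensitive). ``Position Z``, ``Volume``, an ``id`` column
    and any number of numeric intensity columns are optional; a ``label:*``
    column is restored into ``labels``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    xcol = _resolve_column(df.columns, _X_ALIASES)
    ycol = _resolve_column(df.columns, _Y_ALIASES)
    if xcol is None:
        raise TableFormatError(f"{path.name}: missing coordinate column 'Position X'")
    if ycol is None:
        raise TableFormatError(f"{path.name}: missing coordinate column 'Position Y'")
    zcol = _resolve_column(df.columns, _Z_ALIASES)
    vcol = _resolve_column(df.columns, _VOL_ALIASES)
    idcol = _resolve_column(df.columns, _ID_ALIASES)

    special = {xcol, ycol, zcol, vcol, idcol} - {None}
    label_cols = [c for c in df.columns if c.startswith("label:")]
    intensity_cols = [
        c
        for c in df.columns
        if c not in special and c not in label_cols and pd.api.types.is_numeric_dtype(df[c])
    ]

    objects: list[SegmentedObject] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            x = float(rowd[xcol])
            y = float(rowd[ycol])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(f"{path.name}: non-numeric coordinate at row {i}") from exc
        if not (math.isfinite(x) and math.isfinite(y)):
            raise TableFormatError(f"{path.name}: non-finite coordinate at row {i}")
        z = float(rowd[zcol]) if zcol is not None and pd.notna(rowd[zcol]) else None
        vol = float(rowd[vcol]) if vcol is not None and pd.notna(rowd[vcol]) else 0.0
        oid = int(rowd[idcol]) if idcol is not None else i
        intensities = {
            c: float(rowd[c]) for c in intensity_cols if pd.notna(rowd[c])
        }
        labels = {
            c[len("label:"):]: str(rowd[c]) for c in label_cols if pd.notna(rowd[c])
        }
        objects.append(
            SegmentedObject(
                id=oid,
                object_class=object_class,
                x=x,
                y=y,
                z=z,
                volume=vol,
                intensities=intensities,
                labels=labels,
            )
        )
    return objects


def write_objects_table(
    objects: Sequence[SegmentedObject],
    path: str | Path,
    allow_empty: bool = False,
) -> Path:
    """Write a single-class object list as CSV (lossless round trip)."""
    path = Path(path)
    if not objects:
        if not allow_empty:
            raise ValueError("refusing to write an empty object table (set allow_empty)")
        pd.DataFrame(columns=["id", "Position X", "Position Y", "Volume"]).to_csv(
            path, index=False
        )
        return path
    classes = {o.object_class for o in objects}
    if len(classes) > 1:
        raise ValueError(f"mixed object classes in one table: {sorted(classes)}")
    intensity_keys = sorted({k for o in objects for k in o.intensities})
    label_keys = sorted({k for o in objects for k in o.labels})
    records = []
    for o in objects:
        rec: dict[str, object] = {
            "id": o.id,
            "Position X": repr(o.x),
            "Position Y": repr(o.y),
            "Volume": repr(o.volume),
        }
        if o.z is not None:
            rec["Position Z"] = repr(o.z)
        for k in intensity_keys:
            rec[k] = repr(o.intensities[k]) if k in o.intensities else ""
        for k in label_keys:
            rec[f"label:{k}"] = o.labels.get(k, "")
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)
    return path


def _tight_bbox(objects: Iterable[SegmentedObject]) -> tuple[float, float, float, float]:
    xs = [o.x for o in objects]
    ys = [o.y for o in objects]
    if not xs:
        raise ValueError("cannot compute bbox of an empty object list")
    xmin, xmax = min(xs), max(xs)
    ymin, ymax = min(ys), max(ys)
    # Degenerate (single point / collinear) extents padded to positive area.
    if xmax == xmin:
        xmax = xmin + 1.0
    if ymax == ymin:
        ymax = ymin + 1.0
    return (xmin, ymin, xmax, ymax)


def load_sample_folder(
    path: str | Path,
    class_file_map: Mapping[str, str] | None = None,
    bbox: tuple[float, float, float, float] | None = None,
    section_id: str | None = None,
) -> SectionDataset:
    """Load a folder-per-sample layout: one CSV per object class.

    Filenames map to classes via ``class_file_map`` (lower-case stem ->
    class), defaulting to :data:`DEFAULT_CLASS_FILE_MAP`. The bounding box
    defaults to the tight bounds over all loaded objects.
    """
    path = Path(path)
    mapping = dict(DEFAULT_CLASS_FILE_MAP if class_file_map is None else class_file_map)
    objects: list[SegmentedObject] = []
    found = False
    next_id = 0
    for csv_path in sorted(path.glob("*.csv")):
        cls = mapping.get(csv_path.stem.lower())
        if cls is None:
            continue
        found = True
        for obj in read_objects_table(csv_path, cls):
            obj.id = next_id  # re-key: per-file ids may collide across classes
            next_id += 1
            objects.append(obj)
    if not found:
        raise FileNotFoundError(
            f"no recognised class files in {path}; expected one of "
            f"{sorted(mapping)} (.csv)"
        )
    return SectionDataset(
        section_id=section_id or path.name,
        objects=objects,
        bbox=bbox if bbox is not None else _tight_bbox(objects),
    )


def tile_region_to_pseudocells(
    region: Polygon | np.ndarray,
    tile_size: float,
    object_class: str,
    mask_origin: tuple[float, float] = (0.0, 0.0),
    mask_pixel_size: float = 1.0,
    start_id: int = 0,
) -> list[SegmentedObject]:
    """Split an extended structure into tile pseudo-cells.

    Vessel networks and contiguous tumour areas are too large to act as
    "cells" in neighbourhood counting; they are divided into a square grid
    of ``tile_size`` µm anchored at the region's bbox lower-left corner. A
    pseudo-cell is emitted at the centre of every tile whose intersection
    with the region exceeds half a tile area; its volume is the
    intersection area times a unit depth.

    ``region`` is either a shapely polygon (µm) or a boolean mask array
    indexed ``[row, col]`` with ``mask_origin``/``mask_pixel_size`` giving
    its µm frame.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    if isinstance(region, Polygon):
        return _tile_polygon(region, tile_size, object_class, start_id)
    return _tile_mask(
        np.asarray(region, dtype=bool),
        tile_size,
        object_class,
        mask_origin,
        mask_pixel_size,
        start_id,
    )


def _tile_polygon(
    poly: Polygon, tile_size: float, object_class: str, start_id: int
) -> list[SegmentedObject]:
    if poly.is_empty or poly.area == 0:
        return []
    xmin, ymin, xmax, ymax = poly.bounds
    nx = int(math.ceil((xmax - xmin) / tile_size))
    ny = int(math.ceil((ymax - ymin) / tile_size))
    prepared = prep(poly)
    half = tile_size * tile_size / 2.0
    out: list[SegmentedObject] = []
    oid = start_id
    for j in range(ny):
        for i in range(nx):
            x0 = xmin + i * tile_size
            y0 = ymin + j * tile_size
            tile = Polygon(
                [(x0, y0), (x0 + tile_size, y0), (x0 + tile_size, y0 + tile_size), (x0, y0 + tile_size)]
            )
            if not prepared.intersects(tile):
                continue
            inter = poly.intersection(tile).area
            if inter > half:
                out.append(
                    SegmentedObject(
                        id=oid,
                        object_class=object_class,
                        x=x0 + tile_size / 2.0,
                        y=y0 + tile_size / 2.0,
                        volume=inter,
                    )
                )
                oid += 1
    return out


def _tile_mask(
    mask: np.ndarray,
    tile_size: float,
    object_class: str,
    origin: tuple[float, float],
    pixel_size: float,
    start_id: int,
) -> list[SegmentedObject]:
    if mask.size == 0 or not mask.any():
        return []
    rows, cols = np.nonzero(mask)
    px = pixel_size
    # µm bbox of the true region, anchored to pixel edges
    xmin = origin[0] + cols.min() * px
    ymin = origin[1] + rows.min() * px
    xmax = origin[0] + (cols.max() + 1) * px
    ymax = origin[1] + (rows.max() + 1) * px
    nx = int(math.ceil((xmax - xmin) / tile_size))
    ny = int(math.ceil((ymax - ymin) / tile_size))
    # pixel centre coordinates of all true pixels
    cx = origin[0] + (cols + 0.5) * px
    cy = origin[1] + (rows + 0.5) * px
    ti = np.floor((cx - xmin) / tile_size).astype(int)
    tj = np.floor((cy - ymin) / tile_size).astype(int)
    ti = np.clip(ti, 0, nx - 1)
    tj = np.clip(tj, 0, ny - 1)
    areas = np.zeros((ny, nx))
    np.add.at(areas, (tj, ti), px * px)
    half = tile_size * tile_size / 2.0
    out: list[SegmentedObject] = []
    oid = start_id
    for j in range(ny):
        for i in range(nx):
            if areas[j, i] > half:
                out.append(
                    SegmentedObject(
                        id=oid,
                        object_class=object_class,
                        x=xmin + (i + 0.5) * tile_size,
                        y=ymin + (j + 0.5) * tile_size,
                        volume=float(areas[j, i]),
                    )
                )
                oid += 1
    return out
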