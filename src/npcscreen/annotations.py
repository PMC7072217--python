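"""Free-hand polygon annotations: data model, GeoJSON I/O and geometry.

Annotations are simple polygons in pixel coordinates (x to the right, y
down, 0-based).  Each carries one of five annotation kinds; for training the
five kinds collapse onto three classes, with germinal centers and benign
epithelium folded into the benign class, matching how a pathologist finally
labels those regions.

All pixel-membership questions are answered by one rule: a pixel belongs to
a region iff its *center* ``(i + 0.5, j + 0.5)`` lies strictly inside the
polygon.  Window coverage is computed against the union of all same-class
regions, so abutting or duplicated annotations never double-count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

__all__ = [
    "AnnotationKind",
    "TrainingClass",
    "AnnotationRegion",
    "Window",
    "AnnotationFormatError",
    "load_annotations",
    "save_annotations",
    "rasterize",
    "overlap_fraction",
]


class AnnotationKind(str, Enum):
    NPC = "NPC"
    BENIGN_TISSUE = "BENIGN_TISSUE"
    BACKGROUND = "BACKGROUND"
    BENIGN_EPITHELIUM = "BENIGN_EPITHELIUM"
    GERMINAL_CENTER = "GERMINAL_CENTER"


class TrainingClass(int, Enum):
    """3-way training label; integer values index classifier channels."""

    NPC = 0
    BENIGN = 1
    BACKGROUND = 2


#: germinal centers and benign epithelium are benign tissue for training
KIND_TO_CLASS: dict[AnnotationKind, TrainingClass] = {
    AnnotationKind.NPC: TrainingClass.NPC,
    AnnotationKind.BENIGN_TISSUE: TrainingClass.BENIGN,
    AnnotationKind.BENIGN_EPITHELIUM: TrainingClass.BENIGN,
    AnnotationKind.GERMINAL_CENTER: TrainingClass.BENIGN,
    AnnotationKind.BACKGROUND: TrainingClass.BACKGROUND,
}


class AnnotationFormatError(ValueError):
    """Raised for malformed annotation files or invalid polygons."""


@dataclass(frozen=True)
class Window:
    """Half-open square pixel window [x0, x0+size) x [y0, y0+size)."""

    x0: int
    y0: int
    size: int = 256

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("window size must be positive")


@dataclass
class AnnotationRegion:
    """A free-hand polygon annotation with its kind.

    ``polygon`` is an (n, 2) float array of [x, y] vertices (unclosed; the
    closing edge is implicit).  The polygon must be simple and have positive
    area.
    """

    polygon: np.ndarray
    annotation_kind: AnnotationKind
    _shape: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.polygon, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise AnnotationFormatError(
                f"polygon needs >=3 [x, y] vertices, got shape {pts.shape}"
            )
        self.polygon = pts
        self.annotation_kind = AnnotationKind(self.annotation_kind)
        shape = Polygon(pts)
        if not shape.is_valid:
            raise AnnotationFormatError(
                f"polygon is not simple (self-intersecting): {shapely.is_valid_reason(shape)}"
            )
        if shape.area <= 0:
            raise AnnotationFormatError("polygon has zero area")
        self._shape = shape

    @property
    def training_class(self) -> TrainingClass:
        return KIND_TO_CLASS[self.annotation_kind]

    @property
    def shape(self) -> Polygon:
        return self._shape

    @property
    def area(self) -> float:
        return self._shape.area

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy)."""
        return self._shape.bounds


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

_KIND_KEY = "annotation_kind"


def load_annotations(path) -> list[AnnotationRegion]:
    """Read a GeoJSON FeatureCollection of Polygon features.

    Each feature must carry the property ``annotation_kind`` with one of the
    five known kinds; polygons with holes are rejected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationFormatError("expected a GeoJSON FeatureCollection")
    regions = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise AnnotationFormatError(
                f"unsupported geometry type {geom.get('type')!r} (only Polygon)"
            )
        rings = geom.get("coordinates", [])
        if len(rings) != 1:
            raise AnnotationFormatError("polygons with holes are not supported")
        kind_raw = feat.get("properties", {}).get(_KIND_KEY)
        try:
            kind = AnnotationKind(kind_raw)
        except ValueError:
            raise AnnotationFormatError(
                f"unknown annotation_kind {kind_raw!r}; expected one of "
                f"{[k.value for k in AnnotationKind]}"
            ) from None
        ring = np.asarray(rings[0], dtype=np.float64)
        if len(ring) >= 4 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]  # drop GeoJSON closing vertex
        regions.append(AnnotationRegion(ring, kind))
    return regions


def save_annotations(regions: Iterable[AnnotationRegion], path) -> None:
    """Write regions as a GeoJSON FeatureCollection (closed rings)."""
    features = []
    for reg in regions:
        ring = np.vstack([reg.polygon, reg.polygon[:1]])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            "properties": {_KIND_KEY: reg.annotation_kind.value},
        })
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# rasterization and window overlap
# ---------------------------------------------------------------------------


def _class_shapes(regions: Sequence[AnnotationRegion],
                  cls: TrainingClass | None) -> list[Polygon]:
    return [r.shape for r in regions
            if cls is None or r.training_class == TrainingClass(cls)]


def rasterize(regions: Sequence[AnnotationRegion],
              cls: TrainingClass | None,
              bounds: tuple[int, int, int, int]) -> np.ndarray:
    """Pixel-center mask of the union of the class's regions.

    ``bounds`` is (x0, y0, width, height); the mask has shape (height,
    width) with entry (r, c) true iff the center of pixel (x0 + c, y0 + r)
    is strictly inside the union.  ``cls=None`` takes all regions.
    """
    x0, y0, width, height = (int(v) for v in bounds)
    if width <= 0 or height <= 0:
        raise ValueError("bounds must be non-empty")
    mask = np.zeros((height, width), dtype=bool)
    for shape in _class_shapes(regions, cls):
        minx, miny, maxx, maxy = shape.bounds
        # pixel-index range whose centers can possibly fall inside
        c0 = max(int(np.floor(minx - x0 - 0.5)), 0)
        c1 = min(int(np.ceil(maxx - x0 - 0.5)) + 1, width)
        r0 = max(int(np.floor(miny - y0 - 0.5)), 0)
        r1 = min(int(np.ceil(maxy - y0 - 0.5)) + 1, height)
        if c0 >= c1 or r0 >= r1:
            continue
        # 64-bit arithmetic throughout so full-resolution WSIs cannot overflow
        xs = x0 + np.arange(c0, c1, dtype=np.int64) + 0.5
        ys = y0 + np.arange(r0, r1, dtype=np.int64) + 0.5
        gx, gy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(shape, gx.ravel(), gy.ravel())
        mask[r0:r1, c0:c1] |= inside.reshape(r1 - r0, c1 - c0)
    return mask


def overlap_fraction(window: Window,
                     regions: Sequence[AnnotationRegion],
                     cls: TrainingClass | None = None) -> float:
    """Fraction of window pixel centers inside the union of class regions."""
    if not regions:
        return 0.0
    mask = rasterize(regions, cls,
                     (window.x0, window.y0, window.size, window.size))
    return float(mask.mean())


def union_area(regions: Sequence[AnnotationRegion],
               cls: TrainingClass | None = None) -> float:
    """Exact (polygonal) area of the union of the class's regions."""
    shapes = _class_shapes(regions, cls)
    if not shapes:
        return 0.0
    return float(unary_union(shapes).area)
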