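"""Myocardial contour geometry and the three-contour simplification rule.

Contours are closed simple polygons in pixel coordinates (x = column index,
y = row index, pixel centers at integer coordinates).  Vertex order is
normalized to counter-clockwise (positive shoelace area) on construction.

The central operation here is :func:`generate_simplified_set`, which builds a
complete per-frame contour set from only three user-drawn boundaries: the
end-diastolic endocardium and epicardium (the "resting configuration") and
the end-systolic endocardium.  The end-diastolic epicardium is the most
radial extent of the wall over the cycle and is copied to every frame; the
end-systolic endocardium is the most central extent and is copied to every
frame except the resting one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import GeometryError, InsufficientDataError, ValidationError

ENDO = "endocardial"
EPI = "epicardial"
BOUNDARIES = (ENDO, EPI)

FULL_MANUAL = "full_manual"
SIMPLIFIED = "simplified"
PROVENANCES = (FULL_MANUAL, SIMPLIFIED)

# drawn clinical contours carry at least 8 vertices (enforced on file load);
# the in-memory type itself only needs a valid polygon, so that arc-length
# resampling to small n (mesh construction, tests) remains possible
MIN_VERTICES = 8
MIN_POLYGON_VERTICES = 3


def shoelace_area(points: np.ndarray) -> float:
    """Signed polygon area; positive for counter-clockwise vertex order."""
    x = points[:, 0]
    y = points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """A closed simple polygon on one frame (implicitly closed, CCW)."""

    points: np.ndarray
    frame_index: int
    boundary: str

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("contour points must be an (N, 2) array")
        if len(pts) < MIN_POLYGON_VERTICES:
            raise ValidationError(
                f"contour needs at least {MIN_POLYGON_VERTICES} vertices, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValidationError("contour contains non-finite vertices")
        if self.boundary not in BOUNDARIES:
            raise ValidationError(f"unknown boundary type {self.boundary!r}")
        if int(self.frame_index) < 0:
            raise ValidationError("frame_index must be non-negative")
        area = shoelace_area(pts)
        if area == 0.0:
            raise GeometryError("degenerate contour: zero signed area")
        if area < 0.0:  # normalize to counter-clockwise
            pts = pts[::-1].copy()
        poly = Polygon(pts)
        if not poly.is_valid:
            raise GeometryError("contour polygon is not simple (self-intersecting)")
        self.points = pts
        self.frame_index = int(self.frame_index)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return abs(shoelace_area(self.points))

    def copy_to_frame(self, frame_index: int) -> "Contour":
        return replace(self, points=self.points.copy(), frame_index=frame_index)


@dataclass
class ContourSet:
    """Per-frame endo/epi contours with reference (ED) and ES designations."""

    contours: list[Contour] = field(default_factory=list)
    reference_frame: int = 0
    es_frame: Optional[int] = None
    provenance: str = FULL_MANUAL

    def get(self, frame_index: int, boundary: str) -> Optional[Contour]:
        for c in self.contours:
            if c.frame_index == frame_index and c.boundary == boundary:
                return c
        return None

    @property
    def n_frames(self) -> int:
        if not self.contours:
            return 0
        return max(c.frame_index for c in self.contours) + 1

    def frames_with(self, boundary: str) -> list[int]:
        return sorted(c.frame_index for c in self.contours if c.boundary == boundary)

    def validate(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        seen = set()
        for c in self.contours:
            key = (c.frame_index, c.boundary)
            if key in seen:
                raise ValidationError(f"duplicate contour for frame {key[0]} {key[1]}")
            seen.add(key)
        if (self.reference_frame, ENDO) not in seen or (
            self.reference_frame,
            EPI,
        ) not in seen:
            raise ValidationError(
                "reference_frame must carry both an endocardial and an "
                "epicardial contour"
            )
        # full or simplified sets cover every frame with both boundaries
        for f in range(self.n_frames):
            if (f, ENDO) not in seen or (f, EPI) not in seen:
                raise ValidationError(
                    f"frame {f} lacks a boundary (provenance={self.provenance})"
                )
        for f in range(self.n_frames):
            endo = self.get(f, ENDO)
            epi = self.get(f, EPI)
            if endo is not None and epi is not None:
                _require_strictly_inside(endo, epi, f)


def _require_strictly_inside(endo: Contour, epi: Contour, frame: int) -> None:
    if not shapely.contains_properly(epi.polygon, endo.polygon):
        raise GeometryError(
            f"endocardial contour not strictly inside epicardial contour "
            f"on frame {frame}"
        )


def lv_center(contour: Contour) -> tuple[float, float]:
    """Area centroid of the contour polygon (pixel coordinates)."""
    c = contour.polygon.centroid
    return (float(c.x), float(c.y))


def resample_contour(
    contour: Contour,
    n: int,
    start_angle: float = 0.0,
    center: Optional[tuple[float, float]] = None,
) -> Contour:
    """Resample to ``n`` vertices equally spaced by arc length.

    The first output vertex is the closed-polyline point at the arc-length
    position of the input vertex whose polar angle about ``center`` (default:
    area centroid) is nearest ``start_angle`` (radians, measured from the +x
    axis in image coordinates).
    """
    if n < 3:
        raise ValidationError("resample_contour requires n >= 3")
    pts = contour.points
    if center is None:
        center = lv_center(contour)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        raise GeometryError("contour has zero perimeter")
    ang = np.arctan2(pts[:, 1] - center[1], pts[:, 0] - center[0])
    dev = np.mod(ang - start_angle + np.pi, 2 * np.pi) - np.pi
    k = int(np.argmin(np.abs(dev)))
    s0 = cum[k]
    s = np.mod(s0 + total * np.arange(n) / n, total)
    x = np.interp(s, cum, closed[:, 0])
    y = np.interp(s, cum, closed[:, 1])
    return Contour(np.column_stack([x, y]), contour.frame_index, contour.boundary)


def detect_es_frame(contour_set: ContourSet) -> int:
    """End-systolic frame: smallest endocardial area (earliest on ties).

    A single-slice surrogate for "smallest left-ventricular volume".
    """
    frames = contour_set.frames_with(ENDO)
    if len(frames) < 2:
        raise InsufficientDataError(
            "need endocardial contours on at least 2 frames to detect end systole"
        )
    best_frame, best_area = None, np.inf
    for f in frames:
        a = contour_set.get(f, ENDO).area
        if a < best_area:  # strict: earliest frame wins ties
            best_frame, best_area = f, a
    return best_frame


def generate_simplified_set(
    endo_ed: Contour,
    epi_ed: Contour,
    endo_es: Contour,
    n_frames: int,
    reference_frame: int,
    es_frame: int,
) -> ContourSet:
    """Propagate three contours to a full per-frame set.

    The reference (end-diastolic) frame keeps its own endo/epi pair; every
    other frame receives a copy of the end-diastolic epicardium and a copy of
    the end-systolic endocardium.
    """
    if n_frames < 3:
        raise ValidationError("simplified sets require at least 3 frames")
    for name, idx in (("reference_frame", reference_frame), ("es_frame", es_frame)):
        if not (0 <= idx < n_frames):
            raise ValidationError(f"{name}={idx} out of range for {n_frames} frames")
    if reference_frame == es_frame:
        raise ValidationError("reference_frame and es_frame must differ")
    _require_strictly_inside(endo_ed, epi_ed, reference_frame)
    _require_strictly_inside(endo_es, epi_ed, es_frame)

    contours: list[Contour] = []
    for f in range(n_frames):
        epi = epi_ed.copy_to_frame(f)
        epi.boundary = EPI
        contours.append(epi)
        if f == reference_frame:
            endo = endo_ed.copy_to_frame(f)
        else:
            endo = endo_es.copy_to_frame(f)
        endo.boundary = ENDO
        contours.append(endo)
    out = ContourSet(
        contours=contours,
        reference_frame=reference_frame,
        es_frame=es_frame,
        provenance=SIMPLIFIED,
    )
    out.validate()
    return out


@dataclass
class MyocardialMask:
    """Per-frame boolean grid: pixel centers inside epi and not inside endo."""

    masks: np.ndarray  # (n_frames, rows, cols), bool

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def _points_in_polygon(poly: Polygon, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # boundary points count as inside
    return shapely.intersects_xy(poly, x, y)


def rasterize_mask(
    contour_set: ContourSet,
    grid_shape: tuple[int, int],
    n_frames: Optional[int] = None,
) -> MyocardialMask:
    """Pixel-center rasterization of the annulus between endo and epi.

    Pixels exactly on the epicardial boundary are inside the myocardium;
    pixels on the endocardial boundary belong to the cavity.
    """
    rows, cols = grid_shape
    if n_frames is None:
        n_frames = contour_set.n_frames
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    xf = xs.ravel()
    yf = ys.ravel()
    masks = np.zeros((n_frames, rows, cols), dtype=bool)
    for f in range(n_frames):
        endo = contour_set.get(f, ENDO)
        epi = contour_set.get(f, EPI)
        if endo is None or epi is None:
            continue
        inside_epi = _points_in_polygon(epi.polygon, xf, yf)
        inside_endo = _points_in_polygon(endo.polygon, xf, yf)
        m = (inside_epi & ~inside_endo).reshape(rows, cols)
        if not m.any():
            raise ValidationError(
                f"frame {f}: contours produce an empty myocardial mask on the grid"
            )
        masks[f] = m
    return MyocardialMask(masks)
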