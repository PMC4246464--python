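"""Mesh construction, Green-Lagrange strain, segmental curves, twist, torsion.

The myocardium is meshed at the resting (end-diastolic) configuration as a
quadrilateral grid: both boundary contours are resampled to ``n_circ``
arc-length-uniform vertices starting at the anterior right-ventricular
insertion ray, and node ring ``i`` interpolates linearly from endocardium
(``i = 0``) to epicardium (``i = n_rad``).  Defaults are 128 elements
circumferentially and 5 radially.

For each element the deformation gradient ``F`` is estimated at the centroid
by least squares over corner vectors (reference -> deformed), giving the
Green-Lagrange tensor ``E = (F^T F - I) / 2`` — rotation-invariant by
construction.  Normal components are expressed in rest-frame local
directions: radial = outward unit vector from the LV center through the
element centroid, circumferential = its 90-degree counter-clockwise rotation.
Short-axis slices report E_cc and E_rr; long-axis slices report the
wall-tangent component as E_ll.  Values are percentages.

Twist is the mean in-plane rotation of all mesh nodes about the LV center
(degrees, counter-clockwise positive in image coordinates); torsion is the
per-frame ordinary-least-squares slope of twist versus slice location
(deg/cm), with the signed extremum over frames reported as the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import shapely

from . import displacement as _disp
from . import unwrap as _unwrap
from .contours import (
    ENDO,
    EPI,
    Contour,
    ContourSet,
    MyocardialMask,
    lv_center,
    rasterize_mask,
    resample_contour,
    shoelace_area,
)
from .errors import (
    GeometryError,
    InsufficientDataError,
    StageError,
    ValidationError,
)
from .io import LONG_AXIS, SHORT_AXIS, CURVES_COLUMNS, PEAKS_COLUMNS, DenseSlice, StrainTable


# ---------------------------------------------------------------------------
# resting mesh


@dataclass
class RestingMesh:
    """(n_rad + 1) x n_circ node grid between endo and epi, in pixel coords."""

    nodes_px: np.ndarray  # (n_rad + 1, n_circ, 2)
    center_px: tuple[float, float]
    rv_insertion_rad: float
    n_circ: int
    n_rad: int
    e_circ: np.ndarray = field(default=None, repr=False)  # (n_elem, 2)
    e_rad: np.ndarray = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return (self.n_rad + 1) * self.n_circ

    @property
    def n_elements(self) -> int:
        return self.n_rad * self.n_circ

    @property
    def flat_nodes_px(self) -> np.ndarray:
        return self.nodes_px.reshape(-1, 2)

    def element_corner_indices(self) -> np.ndarray:
        """(n_elem, 4) node indices, counter-clockwise within each quad."""
        idx = np.arange(self.n_nodes).reshape(self.n_rad + 1, self.n_circ)
        jp = np.roll(np.arange(self.n_circ), -1)
        corners = np.stack(
            [
                idx[:-1, :],
                idx[1:, :],
                idx[1:, jp],
                idx[:-1, jp],
            ],
            axis=-1,
        )
        return corners.reshape(-1, 4)

    def element_layer(self) -> np.ndarray:
        """Radial layer index (0 = subendocardial) per element."""
        return np.repeat(np.arange(self.n_rad), self.n_circ)

    def element_column(self) -> np.ndarray:
        """Circumferential column index per element."""
        return np.tile(np.arange(self.n_circ), self.n_rad)


def build_resting_mesh(
    endo: Contour,
    epi: Contour,
    n_circ: int = 128,
    n_rad: int = 5,
    rv_insertion: Union[float, tuple[float, float]] = 0.0,
) -> RestingMesh:
    """Mesh the annulus between the resting endo/epi contours.

    ``rv_insertion`` is either an angle in radians (from the +x image axis
    about the LV center) or an (x, y) pixel point converted to that angle;
    the first node column lies on this ray.
    """
    if n_circ < 8 or n_rad < 1:
        raise ValidationError("need n_circ >= 8 and n_rad >= 1")
    center = lv_center(endo)
    if isinstance(rv_insertion, (tuple, list, np.ndarray)):
        px, py = float(rv_insertion[0]), float(rv_insertion[1])
        rv_angle = math.atan2(py - center[1], px - center[0])
    else:
        rv_angle = float(rv_insertion)
    if not shapely.contains_properly(epi.polygon, endo.polygon):
        raise GeometryError("endocardial contour must be strictly inside epicardial")

    endo_r = resample_contour(endo, n_circ, start_angle=rv_angle, center=center)
    epi_r = resample_contour(epi, n_circ, start_angle=rv_angle, center=center)

    frac = np.arange(n_rad + 1)[:, None, None] / n_rad
    nodes = endo_r.points[None, :, :] * (1 - frac) + epi_r.points[None, :, :] * frac

    mesh = RestingMesh(
        nodes_px=nodes,
        center_px=center,
        rv_insertion_rad=rv_angle,
        n_circ=n_circ,
        n_rad=n_rad,
    )
    corners = mesh.flat_nodes_px[mesh.element_corner_indices()]  # (n_elem, 4, 2)
    areas = 0.5 * np.sum(
        corners[:, :, 0] * np.roll(corners[:, :, 1], -1, axis=1)
        - np.roll(corners[:, :, 0], -1, axis=1) * corners[:, :, 1],
        axis=1,
    )
    if np.any(areas <= 0):
        raise GeometryError("mesh contains non-positive-area elements")

    centroids = corners.mean(axis=1)
    radial = centroids - np.asarray(center)[None, :]
    norm = np.linalg.norm(radial, axis=1, keepdims=True)
    if np.any(norm == 0):
        raise GeometryError("element centroid coincides with LV center")
    e_rad = radial / norm  # outward
    e_circ = np.column_stack([-e_rad[:, 1], e_rad[:, 0]])  # 90 deg CCW
    mesh.e_rad = e_rad
    mesh.e_circ = e_circ
    return mesh


# ---------------------------------------------------------------------------
# strain


def deformation_gradients(
    rest_corners: np.ndarray, deformed_corners: np.ndarray
) -> np.ndarray:
    """Least-squares F per element from centroid-relative corner vectors."""
    dX = rest_corners - rest_corners.mean(axis=1, keepdims=True)
    dx = deformed_corners - deformed_corners.mean(axis=1, keepdims=True)
    A = np.einsum("eki,ekj->eij", dx, dX)  # sum dx dX^T
    M = np.einsum("eki,ekj->eij", dX, dX)  # sum dX dX^T
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    if np.any(np.abs(det) < 1e-14):
        raise GeometryError("degenerate element: singular reference geometry")
    Minv = (
        np.stack(
            [
                np.stack([M[:, 1, 1], -M[:, 0, 1]], axis=-1),
                np.stack([-M[:, 1, 0], M[:, 0, 0]], axis=-1),
            ],
            axis=1,
        )
        / det[:, None, None]
    )
    return np.einsum("eij,ejk->eik", A, Minv)


def element_strain(
    rest_corners: np.ndarray,
    deformed_corners: np.ndarray,
    e_circ: np.ndarray,
    e_rad: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Green-Lagrange normal strains (percent) in rest-frame directions."""
    F = deformation_gradients(rest_corners, deformed_corners)
    C = np.einsum("eki,ekj->eij", F, F)  # F^T F
    E = 0.5 * (C - np.eye(2)[None, :, :])
    ecc = 100.0 * np.einsum("ei,eij,ej->e", e_circ, E, e_circ)
    err = 100.0 * np.einsum("ei,eij,ej->e", e_rad, E, e_rad)
    return ecc, err


def segment_of_element(
    n_circ: int, segment_count: int, columns: Optional[np.ndarray] = None
) -> np.ndarray:
    """Assign circumferential columns to equal sectors (first sectors take the
    remainder), starting at the RV insertion column."""
    if segment_count < 1 or segment_count > n_circ:
        raise ValidationError("segment_count must be in [1, n_circ]")
    bounds = np.array_split(np.arange(n_circ), segment_count)
    col_to_seg = np.empty(n_circ, dtype=int)
    for s, cols in enumerate(bounds):
        col_to_seg[cols] = s
    if columns is None:
        return col_to_seg
    return col_to_seg[columns]


def segment_average(
    per_element: np.ndarray, element_segment: np.ndarray, segment_count: int
) -> np.ndarray:
    """Mean over each segment's elements; works on (..., n_elem) arrays."""
    out = np.stack(
        [per_element[..., element_segment == s].mean(axis=-1) for s in range(segment_count)],
        axis=-1,
    )
    return out


def twist_angle(
    rest_nodes: np.ndarray, deformed_nodes: np.ndarray, center: Sequence[float]
) -> float:
    """Mean node rotation about the center, degrees, CCW positive."""
    c = np.asarray(center, dtype=float)
    v0 = np.atleast_2d(rest_nodes) - c
    v1 = np.atleast_2d(deformed_nodes) - c
    cross = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    dot = np.einsum("ij,ij->i", v0, v1)
    return float(np.degrees(np.mean(np.arctan2(cross, dot))))


# ---------------------------------------------------------------------------
# results


@dataclass
class StrainResult:
    """Per-element and per-segment strain curves, twist, and signed peaks."""

    slice_id: str
    orientation: str
    frame_times_ms: np.ndarray
    n_segments: int
    element_segment: np.ndarray
    element_layer: np.ndarray
    ecc_elements: np.ndarray  # (n_frames, n_elem); tangential strain
    err_elements: np.ndarray
    twist_deg: np.ndarray  # (n_frames,)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.ecc_elements.shape[0]

    @property
    def ecc_segments(self) -> np.ndarray:
        return segment_average(self.ecc_elements, self.element_segment, self.n_segments)

    @property
    def err_segments(self) -> np.ndarray:
        return segment_average(self.err_elements, self.element_segment, self.n_segments)

    @property
    def midwall_ecc_curve(self) -> np.ndarray:
        mid = self.element_layer == (self.element_layer.max() // 2)
        return self.ecc_elements[:, mid].mean(axis=1)

    @property
    def peak_midwall_ecc_percent(self) -> float:
        return float(self.midwall_ecc_curve.min())

    @property
    def peak_ecc_per_segment(self) -> np.ndarray:
        return self.ecc_segments.min(axis=0)  # most negative

    @property
    def peak_err_per_segment(self) -> np.ndarray:
        return self.err_segments.max(axis=0)  # most positive

    def to_table(self) -> StrainTable:
        sa = self.orientation == SHORT_AXIS
        ecc = self.ecc_segments
        err = self.err_segments
        rows = []
        for s in range(self.n_segments):
            for f in range(self.n_frames):
                rows.append(
                    {
                        "slice_id": self.slice_id,
                        "segment": s,
                        "frame": f,
                        "time_ms": self.frame_times_ms[f],
                        "Ecc_percent": ecc[f, s] if sa else np.nan,
                        "Err_percent": err[f, s] if sa else np.nan,
                        "Ell_percent": np.nan if sa else ecc[f, s],
                        "twist_deg": self.twist_deg[f],
                    }
                )
        curves = pd.DataFrame(rows, columns=CURVES_COLUMNS)
        nan_col = np.full(self.n_segments, np.nan)
        peaks = pd.DataFrame(
            {
                "slice_id": self.slice_id,
                "segment": np.arange(self.n_segments),
                "peak_Ecc_percent": self.peak_ecc_per_segment if sa else nan_col,
                "peak_Err_percent": self.peak_err_per_segment if sa else nan_col,
                "peak_Ell_percent": nan_col if sa else self.peak_ecc_per_segment,
            },
            columns=PEAKS_COLUMNS,
        )
        return StrainTable(curves=curves, peaks=peaks)


@dataclass
class TorsionResult:
    slice_ids: list[str]
    slice_locations_cm: np.ndarray
    frame_times_ms: np.ndarray
    twist_deg: np.ndarray  # (n_slices, n_frames) on the common grid
    slope_deg_per_cm: np.ndarray  # (n_frames,)

    @property
    def peak_torsion_deg_per_cm(self) -> float:
        k = int(np.argmax(np.abs(self.slope_deg_per_cm)))
        return float(self.slope_deg_per_cm[k])


def torsion_slope(
    twist_curves: Sequence[np.ndarray],
    slice_locations_cm: Sequence[float],
    frame_times_ms: Sequence[np.ndarray],
    slice_ids: Optional[Sequence[str]] = None,
) -> TorsionResult:
    """Per-frame OLS slope of twist (deg) versus slice location (cm)."""
    locs = np.asarray([float(x) for x in slice_locations_cm])
    if len(twist_curves) < 2:
        raise InsufficientDataError("torsion requires at least 2 slices")
    if len(np.unique(locs)) != len(locs):
        raise ValidationError("slice locations must be distinct")
    if len(twist_curves) != len(locs) or len(frame_times_ms) != len(locs):
        raise ValidationError("twist curves, times, and locations must align")

    times = [np.asarray(t, dtype=float) for t in frame_times_ms]
    ref_t = max(times, key=len)
    common = np.empty((len(locs), len(ref_t)))
    for i, (tw, t) in enumerate(zip(twist_curves, times)):
        tw = np.asarray(tw, dtype=float)
        if len(tw) != len(t):
            raise ValidationError(f"slice {i}: twist/time length mismatch")
        if len(t) == len(ref_t) and np.allclose(t, ref_t):
            common[i] = tw
        else:  # resample by linear interpolation in time
            common[i] = np.interp(np.clip(ref_t, t[0], t[-1]), t, tw)

    xc = locs - locs.mean()
    denom = float(np.sum(xc**2))
    slopes = (xc @ common) / denom
    if slice_ids is None:
        slice_ids = [f"slice{i:02d}" for i in range(len(locs))]
    return TorsionResult(
        slice_ids=list(slice_ids),
        slice_locations_cm=locs,
        frame_times_ms=ref_t,
        twist_deg=common,
        slope_deg_per_cm=slopes,
    )


# ---------------------------------------------------------------------------
# the full single-slice pipeline


@dataclass
class AnalysisConfig:
    """Tunables of the post-processing chain (defaults follow the standard
    protocol: 128 x 5 mesh, order-10 temporal polynomial, 6/4 segments)."""

    n_circ: int = 128
    n_rad: int = 5
    segments: Optional[int] = None  # default 6 short-axis / 4 long-axis
    smoothing_order: int = 10
    rv_insertion_deg: float = 0.0
    rbf_smoothing: float = 0.0
    rbf_neighbors: int = 64
    # phase-difference variance above which a pixel counts as noise (rad^2)
    noise_variance_rad2: float = 1.0
    seeds: Optional[list] = None  # explicit per-frame seeds, else auto

    def segment_count(self, orientation: str) -> int:
        if self.segments is not None:
            return self.segments
        return 6 if orientation == SHORT_AXIS else 4


def analyze_slice(
    dense_slice: DenseSlice,
    contour_set: ContourSet,
    config: Optional[AnalysisConfig] = None,
) -> StrainResult:
    """Run the complete chain on one slice: mask -> unwrap -> displacement ->
    trajectories -> smoothing -> mesh deformation -> strain/twist.

    The code path is identical for full-manual and simplified contour sets;
    only the ContourSet differs.
    """
    cfg = config or AnalysisConfig()
    F = dense_slice.n_frames
    try:
        contour_set.validate()
        if contour_set.reference_frame != 0:
            raise ValidationError(
                "analysis assumes the reference (resting) frame is frame 0"
            )
        if contour_set.n_frames < F:
            raise ValidationError(
                f"contours cover {contour_set.n_frames} frames, slice has {F}"
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("validate", exc) from exc

    try:
        mask = rasterize_mask(contour_set, dense_slice.grid_shape, n_frames=F)
    except Exception as exc:  # noqa: BLE001
        raise StageError("mask", exc) from exc

    try:
        endo0 = contour_set.get(0, ENDO)
        epi0 = contour_set.get(0, EPI)
        mesh = build_resting_mesh(
            endo0,
            epi0,
            n_circ=cfg.n_circ,
            n_rad=cfg.n_rad,
            rv_insertion=math.radians(cfg.rv_insertion_deg),
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("mesh", exc) from exc

    try:
        qx = [_unwrap.quality_map(dense_slice.phase_x[f], mask.masks[f]) for f in range(F)]
        qy = [_unwrap.quality_map(dense_slice.phase_y[f], mask.masks[f]) for f in range(F)]
        if cfg.seeds is not None:
            seeds_x = seeds_y = [cfg.seeds for _ in range(F)]
        else:
            seeds_x = _unwrap.plan_seeds(dense_slice.phase_x, mask.masks, qualities=qx)
            seeds_y = _unwrap.plan_seeds(dense_slice.phase_y, mask.masks, qualities=qy)
        ux = np.full(dense_slice.phase_x.shape, np.nan)
        uy = np.full_like(ux, np.nan)
        ux[0] = 0.0
        uy[0] = 0.0
        for f in range(1, F):
            ux[f] = _unwrap.unwrap_region(
                dense_slice.phase_x[f], mask.masks[f], seeds_x[f], quality=qx[f]
            ).unwrapped
            uy[f] = _unwrap.unwrap_region(
                dense_slice.phase_y[f], mask.masks[f], seeds_y[f], quality=qy[f]
            ).unwrapped
    except Exception as exc:  # noqa: BLE001
        raise StageError("unwrap", exc) from exc

    try:
        samples = _disp.samples_from_unwrapped(
            ux,
            uy,
            mask.masks,
            dense_slice.pixel_spacing_mm,
            dense_slice.k_e_cycles_per_mm,
            quality_stacks=(np.stack(qx), np.stack(qy)),
            min_quality=-cfg.noise_variance_rad2,
        )
        node_rest_mm = mesh.flat_nodes_px * dense_slice.pixel_spacing_mm
        trajectories = _disp.build_trajectories(
            samples,
            node_rest_mm,
            dense_slice.frame_times_ms,
            smoothing=cfg.rbf_smoothing,
            neighbors=cfg.rbf_neighbors,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("displacement", exc) from exc

    try:
        trajectories = _disp.smooth_trajectories(trajectories, order=cfg.smoothing_order)
    except Exception as exc:  # noqa: BLE001
        raise StageError("smoothing", exc) from exc

    try:
        corners_idx = mesh.element_corner_indices()
        rest_mm = node_rest_mm[corners_idx]
        center_mm = np.asarray(mesh.center_px) * dense_slice.pixel_spacing_mm
        n_elem = mesh.n_elements
        ecc = np.zeros((F, n_elem))
        err = np.zeros((F, n_elem))
        twist = np.zeros(F)
        for f in range(1, F):
            deformed = trajectories.positions[f][corners_idx]
            ecc[f], err[f] = element_strain(rest_mm, deformed, mesh.e_circ, mesh.e_rad)
            twist[f] = twist_angle(node_rest_mm, trajectories.positions[f], center_mm)
        seg_count = cfg.segment_count(dense_slice.orientation)
        elem_seg = segment_of_element(cfg.n_circ, seg_count, mesh.element_column())
    except Exception as exc:  # noqa: BLE001
        raise StageError("strain", exc) from exc

    n_src = 3 if contour_set.provenance == "simplified" else 2 * contour_set.n_frames
    diagnostics = {
        "contours_consumed": n_src,
        "samples_per_frame": [len(p) for p in samples.positions_mm],
        "extrapolated_nodes_per_frame": trajectories.extrapolated.sum(axis=1).tolist()
        if trajectories.extrapolated is not None
        else None,
    }
    return StrainResult(
        slice_id=dense_slice.slice_id,
        orientation=dense_slice.orientation,
        frame_times_ms=dense_slice.frame_times_ms,
        n_segments=seg_count,
        element_segment=elem_seg,
        element_layer=mesh.element_layer(),
        ecc_elements=ecc,
        err_elements=err,
        twist_deg=twist,
        diagnostics=diagnostics,
    )


def analyze_study(
    slices: Sequence[DenseSlice],
    contour_sets: Sequence[ContourSet],
    config: Optional[AnalysisConfig] = None,
) -> tuple[list[StrainResult], Optional[TorsionResult]]:
    """Analyze several slices; compute torsion when >= 2 distinct locations."""
    if len(slices) != len(contour_sets):
        raise ValidationError("need one contour set per slice")
    results = [analyze_slice(s, c, config) for s, c in zip(slices, contour_sets)]
    torsion = None
    locs = [s.slice_location_cm for s in slices]
    if len(slices) >= 2 and len(set(locs)) == len(locs):
        torsion = torsion_slope(
            [r.twist_deg for r in results],
            locs,
            [s.frame_times_ms for s in slices],
            slice_ids=[s.slice_id for s in slices],
        )
    return results, torsion
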