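"""From unwrapped phase to smoothed material-point trajectories.

DENSE phase at a pixel encodes the displacement, since the end-diastolic
reference, of the tissue *currently* at that pixel: ``u = phi / (2*pi*k_e)``
per in-plane encoding direction.  Samples therefore live at deformed
(Eulerian) positions; to deform a mesh defined at rest we invert the
relation by scattered interpolation over (reference position ``X = p - u``
-> displacement ``u``) pairs, using a thin-plate-spline radial kernel with a
linear polynomial tail (exact on constant and affine fields, exact at the
samples when noise-free).  Queries falling outside the convex hull of the
samples take the nearest sample's value and are flagged.

Each mesh node's trajectory is then smoothed with a least-squares polynomial
in normalized time (default order 10, clamped to n_frames - 2 for
conditioning at low frame counts).  The fit uses a zero-intercept basis on
displacement, pinning every trajectory to its resting position at frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import InsufficientDataError, ValidationError


def phase_to_displacement(unwrapped_phase, k_e_cycles_per_mm: float):
    """u[mm] = phi / (2*pi*k_e), per encoding direction."""
    if k_e_cycles_per_mm <= 0:
        raise ValidationError("k_e must be positive")
    return np.asarray(unwrapped_phase, dtype=float) / (
        2.0 * np.pi * k_e_cycles_per_mm
    )


@dataclass
class PixelDisplacementSamples:
    """Per-frame scattered samples: current position p and displacement u (mm).

    Frame 0 is the reference: its displacements are identically zero."""

    positions_mm: list[np.ndarray]  # each (N_f, 2)
    displacements_mm: list[np.ndarray]  # each (N_f, 2)

    def __post_init__(self):
        if len(self.positions_mm) != len(self.displacements_mm):
            raise ValidationError("positions/displacements frame counts differ")
        for f, (p, u) in enumerate(zip(self.positions_mm, self.displacements_mm)):
            if p.shape != u.shape or p.ndim != 2 or p.shape[1] != 2:
                raise ValidationError(f"frame {f}: samples must be (N, 2) arrays")
            if not (np.all(np.isfinite(p)) and np.all(np.isfinite(u))):
                raise ValidationError(f"frame {f}: non-finite sample values")
        if len(self.positions_mm) and np.any(self.displacements_mm[0] != 0.0):
            raise ValidationError("frame 0 displacements must be identically zero")

    @property
    def n_frames(self) -> int:
        return len(self.positions_mm)

    def reference_positions(self, frame: int) -> np.ndarray:
        """X = p - u: resting position of each sampled tissue element."""
        return self.positions_mm[frame] - self.displacements_mm[frame]


def samples_from_unwrapped(
    unwrapped_x: np.ndarray,
    unwrapped_y: np.ndarray,
    masks: np.ndarray,
    pixel_spacing_mm: float,
    k_e_cycles_per_mm: float,
    quality_stacks: Optional[tuple] = None,
    min_quality: Optional[float] = None,
) -> PixelDisplacementSamples:
    """Collect (position, displacement) samples from unwrapped phase stacks.

    Optionally drops pixels whose phase-difference variance marks them as
    noise (quality below ``min_quality`` in either encoding direction).
    Frame 0 contributes zero displacement at every masked pixel by the
    reference convention.
    """
    F = masks.shape[0]
    positions, displacements = [], []
    for f in range(F):
        keep = masks[f] & np.isfinite(unwrapped_x[f]) & np.isfinite(unwrapped_y[f])
        if min_quality is not None and quality_stacks is not None:
            qx, qy = quality_stacks
            keep = keep & (qx[f] >= min_quality) & (qy[f] >= min_quality)
        rr, cc = np.nonzero(keep)
        pos = np.column_stack([cc, rr]).astype(float) * pixel_spacing_mm
        if f == 0:
            u = np.zeros_like(pos)
        else:
            ux = phase_to_displacement(unwrapped_x[f][rr, cc], k_e_cycles_per_mm)
            uy = phase_to_displacement(unwrapped_y[f][rr, cc], k_e_cycles_per_mm)
            u = np.column_stack([ux, uy])
        positions.append(pos)
        displacements.append(u)
    return PixelDisplacementSamples(positions, displacements)


def forward_displacement_at(
    samples: PixelDisplacementSamples,
    frame: int,
    query_points_mm: np.ndarray,
    smoothing: float = 0.0,
    neighbors: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement at resting-position queries, via scattered interpolation.

    Returns ``(u, extrapolated)`` where ``extrapolated`` flags queries outside
    the convex hull of the sampled reference positions (those take the
    nearest sample's displacement).
    """
    X = samples.reference_positions(frame)
    U = samples.displacements_mm[frame]
    query = np.atleast_2d(np.asarray(query_points_mm, dtype=float))
    if len(X) < 3:
        raise InsufficientDataError(
            f"frame {frame}: need >= 3 displacement samples, got {len(X)}"
        )
    centered = X - X.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise InsufficientDataError(f"frame {frame}: samples are collinear")

    nb = min(neighbors, len(X))
    interp = RBFInterpolator(
        X, U, kernel="thin_plate_spline", degree=1, smoothing=smoothing, neighbors=nb
    )
    u = interp(query)

    extrapolated = np.zeros(len(query), dtype=bool)
    try:
        tri = Delaunay(X)
        extrapolated = tri.find_simplex(query) < 0
    except QhullError:  # degenerate sample geometry: treat all as interior
        pass
    if extrapolated.any():
        tree = cKDTree(X)
        _, nearest = tree.query(query[extrapolated])
        u[extrapolated] = U[nearest]
    return u, extrapolated


@dataclass
class TrajectorySet:
    """Per-node positions over time, raw and (optionally) smoothed."""

    frame_times_ms: np.ndarray
    raw_positions_mm: np.ndarray  # (n_frames, n_nodes, 2)
    smoothed_positions_mm: Optional[np.ndarray] = None
    coefficients: Optional[np.ndarray] = None  # (degree, n_nodes, 2)
    extrapolated: Optional[np.ndarray] = None  # (n_frames, n_nodes) bool

    @property
    def n_frames(self) -> int:
        return self.raw_positions_mm.shape[0]

    @property
    def resting_positions_mm(self) -> np.ndarray:
        return self.raw_positions_mm[0]

    @property
    def positions(self) -> np.ndarray:
        if self.smoothed_positions_mm is not None:
            return self.smoothed_positions_mm
        return self.raw_positions_mm


def build_trajectories(
    samples: PixelDisplacementSamples,
    node_rest_positions_mm: np.ndarray,
    frame_times_ms: np.ndarray,
    smoothing: float = 0.0,
    neighbors: int = 64,
) -> TrajectorySet:
    """Deform resting nodes along the interpolated displacement field."""
    nodes = np.atleast_2d(np.asarray(node_rest_positions_mm, dtype=float))
    F = samples.n_frames
    if F != len(frame_times_ms):
        raise ValidationError("frame_times_ms length must match sample frames")
    pos = np.empty((F, len(nodes), 2))
    flags = np.zeros((F, len(nodes)), dtype=bool)
    pos[0] = nodes  # reference frame: zero displacement exactly
    for f in range(1, F):
        u, ex = forward_displacement_at(
            samples, f, nodes, smoothing=smoothing, neighbors=neighbors
        )
        pos[f] = nodes + u
        flags[f] = ex
    return TrajectorySet(
        frame_times_ms=np.asarray(frame_times_ms, dtype=float),
        raw_positions_mm=pos,
        extrapolated=flags,
    )


def smooth_trajectories(trajectories: TrajectorySet, order: int = 10) -> TrajectorySet:
    """Least-squares polynomial smoothing of each node trajectory.

    Degree = min(order, n_frames - 2), fit in normalized time on the
    displacement from rest with a zero-intercept basis (t, t^2, ..., t^d), so
    the smoothed trajectory passes exactly through the resting position at
    frame 0.
    """
    if order < 1:
        raise ValidationError("smoothing order must be >= 1")
    F = trajectories.n_frames
    if F < 3:
        raise InsufficientDataError("smoothing needs at least 3 frames")
    degree = max(1, min(order, F - 2))
    times = trajectories.frame_times_ms
    t = (times - times[0]) / (times[-1] - times[0])
    V = np.column_stack([t ** k for k in range(1, degree + 1)])  # no constant term

    rest = trajectories.resting_positions_mm
    disp = trajectories.raw_positions_mm - rest[None, :, :]
    B = disp.reshape(F, -1)
    coef, *_ = np.linalg.lstsq(V, B, rcond=None)
    smooth = (V @ coef).reshape(F, -1, 2) + rest[None, :, :]
    smooth[0] = rest
    return TrajectorySet(
        frame_times_ms=times,
        raw_positions_mm=trajectories.raw_positions_mm,
        smoothed_positions_mm=smooth,
        coefficients=coef.reshape(degree, -1, 2),
        extrapolated=trajectories.extrapolated,
    )
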