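"""Analytic cine DENSE phantom: an incompressible, contracting, twisting annulus.

The phantom plays the role of an acquisition with exactly known mechanics.
A short-axis left ventricle is modelled as an annulus (resting radii
``R_endo_mm`` < ``R_epi_mm``) deforming in-plane with

* a temporal amplitude ``a(f)`` rising smoothly from 0 at frame 0 to 1 at
  the peak-systolic frame and falling symmetrically back to 0 at the last
  frame (sinusoidal half-waves, so ground truth is a documented closed form);
* an area-preserving radial map ``r(R, f) = sqrt(R^2 - R_endo^2 + r_endo(f)^2)``
  with ``r_endo(f) = R_endo * (1 - c * a(f))`` (2D incompressibility);
* a rigid in-plane rotation by ``a(f) * twist_peak_deg`` about the center.

Displacement is encoded into phase exactly as DENSE does: the tissue found at
pixel ``p`` on frame ``f`` carries ``phi_d = wrap(2*pi*k_e*u_d + noise)`` per
in-plane direction ``d``, where ``u = p - X(p, f)`` is its displacement since
the reference (end-diastolic) configuration, measured at its current
position.  Pixels outside the myocardium carry uniform random phase (pure
phase noise) and low magnitude.

Closed-form circumferential/radial Green-Lagrange strains and the per-frame
twist are available for every resting radius, making the phantom the oracle
for strain and torsion recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .contours import ENDO, EPI, FULL_MANUAL, Contour, ContourSet
from .errors import ValidationError
from .io import SHORT_AXIS, ORIENTATIONS, DenseSlice, wrap_phase


@dataclass
class PhantomSpec:
    """All parameters of one phantom slice (defaults: mouse-like acquisition)."""

    grid: tuple[int, int] = (128, 128)  # rows, cols
    pixel_spacing_mm: float = 0.25
    n_frames: int = 20
    R_endo_mm: float = 8.0
    R_epi_mm: float = 12.0
    contraction_peak: float = 0.2  # endo radius at peak = (1 - c) * R_endo
    twist_peak_deg: float = 4.0
    systole_fraction: float = 0.45
    k_e_cycles_per_mm: float = 1.0
    phase_noise_sd_rad: float = 0.05
    seed: int = 1
    slice_location_cm: float = 0.0
    frame_interval_ms: float = 7.4
    orientation: str = SHORT_AXIS
    slice_id: str = "slice00"
    center_px: Optional[tuple[float, float]] = None  # default: grid center

    def __post_init__(self):
        rows, cols = self.grid
        if self.center_px is None:
            self.center_px = ((cols - 1) / 2.0, (rows - 1) / 2.0)
        if not (0.0 < self.R_endo_mm < self.R_epi_mm):
            raise ValidationError("need 0 < R_endo_mm < R_epi_mm")
        if not (0.0 <= self.contraction_peak < 1.0):
            raise ValidationError("contraction_peak must lie in [0, 1)")
        if self.phase_noise_sd_rad < 0:
            raise ValidationError("phase_noise_sd_rad must be >= 0")
        if self.n_frames < 3:
            raise ValidationError("n_frames must be >= 3")
        if not (0.0 < self.systole_fraction < 1.0):
            raise ValidationError("systole_fraction must lie in (0, 1)")
        if self.pixel_spacing_mm <= 0 or self.k_e_cycles_per_mm <= 0:
            raise ValidationError("pixel_spacing_mm and k_e must be positive")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")
        cx, cy = self.center_px
        r_px = self.R_epi_mm / self.pixel_spacing_mm
        if cx - r_px < 0 or cy - r_px < 0 or cx + r_px > cols - 1 or cy + r_px > rows - 1:
            raise ValidationError("epicardium does not fit inside the image grid")

    @property
    def peak_frame(self) -> int:
        p = int(round(self.systole_fraction * (self.n_frames - 1)))
        return min(max(p, 1), self.n_frames - 2)

    @property
    def center_mm(self) -> tuple[float, float]:
        return (
            self.center_px[0] * self.pixel_spacing_mm,
            self.center_px[1] * self.pixel_spacing_mm,
        )


def amplitude(spec: PhantomSpec, frame: int) -> float:
    """Temporal deformation amplitude a(f): 0 at f=0, 1 at the peak frame,
    back to 0 at the last frame (sin^2 half-waves, C1-continuous)."""
    if not (0 <= frame < spec.n_frames):
        raise ValidationError(f"frame {frame} out of range")
    p = spec.peak_frame
    if frame <= p:
        x = frame / p
    else:
        x = (spec.n_frames - 1 - frame) / (spec.n_frames - 1 - p)
    return math.sin(0.5 * math.pi * x) ** 2


def r_endo_at(spec: PhantomSpec, frame: int) -> float:
    return spec.R_endo_mm * (1.0 - spec.contraction_peak * amplitude(spec, frame))


def r_of_R(spec: PhantomSpec, frame: int, R) -> np.ndarray:
    """Area-preserving radial map of the annulus (valid for R >= R_endo)."""
    re = r_endo_at(spec, frame)
    return np.sqrt(np.maximum(np.square(R) - spec.R_endo_mm**2 + re**2, 0.0))


def R_of_r(spec: PhantomSpec, frame: int, r) -> np.ndarray:
    re = r_endo_at(spec, frame)
    return np.sqrt(np.maximum(np.square(r) - re**2 + spec.R_endo_mm**2, 0.0))


def deformation_at(spec: PhantomSpec, frame: int):
    """Forward map X -> x (mm coordinates) and the scalar amplitude a(f)."""
    a = amplitude(spec, frame)
    rot = math.radians(spec.twist_peak_deg) * a
    cx, cy = spec.center_mm

    def forward(points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        R = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx) + rot
        r = r_of_R(spec, frame, R)
        return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])

    return forward, a


def inverse_deformation_at(spec: PhantomSpec, frame: int):
    """Inverse map x -> X: resting position of the tissue now at x."""
    a = amplitude(spec, frame)
    rot = math.radians(spec.twist_peak_deg) * a
    cx, cy = spec.center_mm

    def inverse(points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        dx = pts[:, 0] - cx
        dy = pts[:, 1] - cy
        r = np.hypot(dx, dy)
        theta = np.arctan2(dy, dx) - rot
        R = R_of_r(spec, frame, r)
        return np.column_stack([cx + R * np.cos(theta), cy + R * np.sin(theta)])

    return inverse


def ground_truth_strain(spec: PhantomSpec, frame: int, R: float) -> tuple[float, float]:
    """Closed-form (Ecc, Err) in percent at resting radius R (mm).

    Circumferential stretch lambda_c = r(R, f)/R; incompressibility gives the
    radial stretch lambda_r = 1/lambda_c.  E = (lambda^2 - 1)/2, in percent.
    """
    if not (spec.R_endo_mm <= R <= spec.R_epi_mm):
        raise ValidationError("R outside the resting wall")
    lam_c = float(r_of_R(spec, frame, R)) / R
    lam_r = 1.0 / lam_c
    return (100.0 * 0.5 * (lam_c**2 - 1.0), 100.0 * 0.5 * (lam_r**2 - 1.0))


def _circle_contour(
    spec: PhantomSpec, radius_mm: float, frame: int, boundary: str, n: int = 96
) -> Contour:
    cx, cy = spec.center_px
    r_px = radius_mm / spec.pixel_spacing_mm
    th = 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([cx + r_px * np.cos(th), cy + r_px * np.sin(th)])
    return Contour(pts, frame, boundary)


def truth_contours(spec: PhantomSpec, n_vertices: int = 96) -> ContourSet:
    """Exact per-frame boundaries sampled from the analytic annulus."""
    contours = []
    for f in range(spec.n_frames):
        re = r_endo_at(spec, f)
        rp = float(r_of_R(spec, f, spec.R_epi_mm))
        contours.append(_circle_contour(spec, re, f, ENDO, n_vertices))
        contours.append(_circle_contour(spec, rp, f, EPI, n_vertices))
    out = ContourSet(
        contours=contours,
        reference_frame=0,
        es_frame=spec.peak_frame,
        provenance=FULL_MANUAL,
    )
    out.validate()
    return out


@dataclass
class GroundTruth:
    """Everything known analytically about one rendered phantom slice."""

    spec: PhantomSpec
    contour_set: ContourSet = field(repr=False)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([amplitude(self.spec, f) for f in range(self.spec.n_frames)])

    @property
    def twist_deg(self) -> np.ndarray:
        return self.amplitudes * self.spec.twist_peak_deg

    @property
    def r_endo_mm(self) -> np.ndarray:
        return np.array([r_endo_at(self.spec, f) for f in range(self.spec.n_frames)])

    @property
    def r_epi_mm(self) -> np.ndarray:
        return np.array(
            [float(r_of_R(self.spec, f, self.spec.R_epi_mm)) for f in range(self.spec.n_frames)]
        )

    def forward(self, frame: int) -> Callable[[np.ndarray], np.ndarray]:
        return deformation_at(self.spec, frame)[0]

    def inverse(self, frame: int) -> Callable[[np.ndarray], np.ndarray]:
        return inverse_deformation_at(self.spec, frame)

    def strain(self, frame: int, R: float) -> tuple[float, float]:
        return ground_truth_strain(self.spec, frame, R)

    @property
    def midwall_radius_mm(self) -> float:
        return 0.5 * (self.spec.R_endo_mm + self.spec.R_epi_mm)

    def midwall_strain_curves(self) -> tuple[np.ndarray, np.ndarray]:
        ecc, err = zip(
            *(self.strain(f, self.midwall_radius_mm) for f in range(self.spec.n_frames))
        )
        return np.array(ecc), np.array(err)

    @property
    def peak_midwall_ecc_percent(self) -> float:
        return float(self.midwall_strain_curves()[0].min())

    @property
    def peak_midwall_err_percent(self) -> float:
        return float(self.midwall_strain_curves()[1].max())


def render_slice(spec: PhantomSpec) -> tuple[DenseSlice, GroundTruth]:
    """Render magnitude + wrapped-phase stacks; deterministic given spec.seed."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid
    sp = spec.pixel_spacing_mm
    cx, cy = spec.center_mm
    xs, ys = np.meshgrid(np.arange(cols, dtype=float), np.arange(rows, dtype=float))
    px = xs * sp
    py = ys * sp
    dx = px - cx
    dy = py - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    F = spec.n_frames
    magnitude = np.empty((F, rows, cols))
    phase_x = np.empty((F, rows, cols))
    phase_y = np.empty((F, rows, cols))
    two_pi_ke = 2.0 * np.pi * spec.k_e_cycles_per_mm

    for f in range(F):
        a = amplitude(spec, f)
        rot = math.radians(spec.twist_peak_deg) * a
        re = r_endo_at(spec, f)
        rp = float(r_of_R(spec, f, spec.R_epi_mm))
        in_myo = (r >= re) & (r <= rp)
        # resting position of the tissue currently at each pixel
        R = R_of_r(spec, f, r)
        TH = theta - rot
        ux = px - (cx + R * np.cos(TH))
        uy = py - (cy + R * np.sin(TH))
        # fixed draw order per frame keeps output reproducible
        eps_x = rng.normal(0.0, spec.phase_noise_sd_rad, (rows, cols))
        eps_y = rng.normal(0.0, spec.phase_noise_sd_rad, (rows, cols))
        noise_x = rng.uniform(-np.pi, np.pi, (rows, cols))
        noise_y = rng.uniform(-np.pi, np.pi, (rows, cols))
        phase_x[f] = np.where(in_myo, wrap_phase(two_pi_ke * ux + eps_x), noise_x)
        phase_y[f] = np.where(in_myo, wrap_phase(two_pi_ke * uy + eps_y), noise_y)
        magnitude[f] = np.where(in_myo, 1.0, 0.05)

    dense = DenseSlice(
        magnitude=magnitude,
        phase_x=wrap_phase(phase_x),
        phase_y=wrap_phase(phase_y),
        pixel_spacing_mm=sp,
        k_e_cycles_per_mm=spec.k_e_cycles_per_mm,
        frame_times_ms=np.arange(F) * spec.frame_interval_ms,
        slice_location_cm=spec.slice_location_cm,
        orientation=spec.orientation,
        slice_id=spec.slice_id,
    )
    return dense, GroundTruth(spec=spec, contour_set=truth_contours(spec))


def render_study(
    base: PhantomSpec,
    slice_locations_cm: Sequence[float],
    torsion_deg_per_cm: float,
) -> tuple[list[tuple[DenseSlice, GroundTruth]], float]:
    """Render a multi-slice study with a linear twist gradient along the axis.

    Slice i gets twist_peak = base.twist_peak_deg + torsion * location_i, so
    the true torsion (slope of peak twist vs location) is the requested value.
    """
    locs = [float(x) for x in slice_locations_cm]
    if len(locs) < 2:
        raise ValidationError("a study needs at least 2 slice locations")
    if len(set(locs)) != len(locs):
        raise ValidationError("slice locations must be distinct")
    out = []
    for i, loc in enumerate(locs):
        spec_i = replace(
            base,
            slice_location_cm=loc,
            twist_peak_deg=base.twist_peak_deg + torsion_deg_per_cm * loc,
            seed=base.seed + i,
            slice_id=f"slice{i:02d}",
        )
        out.append(render_slice(spec_i))
    return out, float(torsion_deg_per_cm)
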