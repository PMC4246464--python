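"""File formats: HDF5 slice container, contour JSON, strain CSV tables.

All file handling is isolated here so the computational core works purely on
in-memory arrays.  Layouts:

Container (HDF5)
    ``/slices/<slice_id>/{magnitude, phase_x, phase_y}`` as frames x rows x
    cols arrays; per-slice attributes ``pixel_spacing_mm``,
    ``k_e_cycles_per_mm``, ``frame_times_ms``, ``slice_location_cm``,
    ``orientation``.  A root attribute ``slice_order`` preserves slice order.

Contour JSON
    ``{"reference_frame": int, "es_frame": int|null, "provenance": str,
    "contours": [{"frame": int, "boundary": str, "points": [[x, y], ...]}]}``

Curves CSV header
    ``slice_id,segment,frame,time_ms,Ecc_percent,Err_percent,Ell_percent,twist_deg``
    (the strain column that does not apply to the slice orientation is empty).
Peaks CSV header
    ``slice_id,segment,peak_Ecc_percent,peak_Err_percent,peak_Ell_percent``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .contours import Contour, ContourSet
from .errors import SchemaError, ValidationError

SHORT_AXIS = "short_axis"
LONG_AXIS = "long_axis"
ORIENTATIONS = (SHORT_AXIS, LONG_AXIS)

_REQUIRED_DATASETS = ("magnitude", "phase_x", "phase_y")
_REQUIRED_ATTRS = (
    "pixel_spacing_mm",
    "k_e_cycles_per_mm",
    "frame_times_ms",
    "slice_location_cm",
    "orientation",
)

CURVES_COLUMNS = [
    "slice_id",
    "segment",
    "frame",
    "time_ms",
    "Ecc_percent",
    "Err_percent",
    "Ell_percent",
    "twist_deg",
]
PEAKS_COLUMNS = [
    "slice_id",
    "segment",
    "peak_Ecc_percent",
    "peak_Err_percent",
    "peak_Ell_percent",
]


def wrap_phase(x):
    """Wrap phase into [-pi, pi): ((x + pi) mod 2*pi) - pi."""
    return np.mod(np.asarray(x, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class DenseSlice:
    """One imaging slice: magnitude + wrapped-phase stacks with metadata."""

    magnitude: np.ndarray  # (frames, rows, cols)
    phase_x: np.ndarray  # radians in [-pi, pi)
    phase_y: np.ndarray
    pixel_spacing_mm: float
    k_e_cycles_per_mm: float
    frame_times_ms: np.ndarray
    slice_location_cm: float = 0.0
    orientation: str = SHORT_AXIS
    slice_id: str = "slice00"

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_x = np.asarray(self.phase_x, dtype=float)
        self.phase_y = np.asarray(self.phase_y, dtype=float)
        self.frame_times_ms = np.asarray(self.frame_times_ms, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.magnitude.ndim != 3:
            raise ValidationError("image stacks must be frames x rows x cols")
        if not (self.magnitude.shape == self.phase_x.shape == self.phase_y.shape):
            raise ValidationError("magnitude/phase_x/phase_y shapes differ")
        if self.n_frames < 3:
            raise ValidationError("a slice needs at least 3 frames")
        for name, arr in (("phase_x", self.phase_x), ("phase_y", self.phase_y)):
            if np.any(arr < -np.pi) or np.any(arr >= np.pi):
                raise ValidationError(f"{name} values must lie in [-pi, pi)")
        if not self.pixel_spacing_mm > 0:
            raise ValidationError("pixel_spacing_mm must be positive")
        if not self.k_e_cycles_per_mm > 0:
            raise ValidationError("k_e_cycles_per_mm must be positive")
        if len(self.frame_times_ms) != self.n_frames:
            raise ValidationError("frame_times_ms length must equal frame count")
        if np.any(np.diff(self.frame_times_ms) <= 0):
            raise ValidationError("frame_times_ms must be strictly increasing")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.magnitude.shape[1:]


def write_dense_container(slices: Sequence[DenseSlice], path) -> None:
    slices = list(slices)
    if not slices:
        raise ValidationError("nothing to write: empty slice collection")
    ids = [s.slice_id for s in slices]
    if len(set(ids)) != len(ids):
        raise ValidationError("slice_id values must be unique")
    for s in slices:
        s.validate()
    with h5py.File(path, "w") as f:
        f.attrs["slice_order"] = ids
        root = f.create_group("slices")
        for s in slices:
            g = root.create_group(s.slice_id)
            for name in _REQUIRED_DATASETS:
                # track_times=False keeps files bit-identical across runs
                g.create_dataset(name, data=getattr(s, name), track_times=False)
            g.attrs["pixel_spacing_mm"] = float(s.pixel_spacing_mm)
            g.attrs["k_e_cycles_per_mm"] = float(s.k_e_cycles_per_mm)
            g.attrs["frame_times_ms"] = np.asarray(s.frame_times_ms, dtype=float)
            g.attrs["slice_location_cm"] = float(s.slice_location_cm)
            g.attrs["orientation"] = s.orientation


def read_dense_container(path) -> list[DenseSlice]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"container not found: {path}")
    out: list[DenseSlice] = []
    with h5py.File(path, "r") as f:
        if "slices" not in f:
            raise SchemaError("missing required group 'slices'")
        root = f["slices"]
        order = list(f.attrs.get("slice_order", sorted(root.keys())))
        order = [s.decode() if isinstance(s, bytes) else str(s) for s in order]
        for sid in order:
            if sid not in root:
                raise SchemaError(f"slice_order names missing group '{sid}'")
            g = root[sid]
            arrays = {}
            for name in _REQUIRED_DATASETS:
                if name not in g:
                    raise SchemaError(f"slice '{sid}' missing dataset '{name}'")
                arrays[name] = np.asarray(g[name], dtype=float)
            attrs = {}
            for name in _REQUIRED_ATTRS:
                if name not in g.attrs:
                    raise SchemaError(f"slice '{sid}' missing attribute '{name}'")
                attrs[name] = g.attrs[name]
            orientation = attrs["orientation"]
            if isinstance(orientation, bytes):
                orientation = orientation.decode()
            out.append(
                DenseSlice(
                    magnitude=arrays["magnitude"],
                    phase_x=wrap_phase(arrays["phase_x"]),
                    phase_y=wrap_phase(arrays["phase_y"]),
                    pixel_spacing_mm=float(attrs["pixel_spacing_mm"]),
                    k_e_cycles_per_mm=float(attrs["k_e_cycles_per_mm"]),
                    frame_times_ms=np.asarray(attrs["frame_times_ms"], dtype=float),
                    slice_location_cm=float(attrs["slice_location_cm"]),
                    orientation=str(orientation),
                    slice_id=sid,
                )
            )
    return out


def write_contours(contour_set: ContourSet, path) -> None:
    doc = {
        "reference_frame": int(contour_set.reference_frame),
        "es_frame": None
        if contour_set.es_frame is None
        else int(contour_set.es_frame),
        "provenance": contour_set.provenance,
        "contours": [
            {
                "frame": int(c.frame_index),
                "boundary": c.boundary,
                "points": [[float(x), float(y)] for x, y in c.points],
            }
            for c in contour_set.contours
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_contours(path, validate: bool = True) -> ContourSet:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"contour file not found: {path}")
    doc = json.loads(path.read_text())
    for key in ("reference_frame", "provenance", "contours"):
        if key not in doc:
            raise SchemaError(f"contour file missing key '{key}'")
    contours = []
    for i, rec in enumerate(doc["contours"]):
        for key in ("frame", "boundary", "points"):
            if key not in rec:
                raise SchemaError(f"contour record {i} missing key '{key}'")
        if len(rec["points"]) < 8:
            raise ValidationError(
                f"contour record {i} has {len(rec['points'])} vertices; "
                "drawn contours need at least 8"
            )
        contours.append(
            Contour(
                points=np.asarray(rec["points"], dtype=float),
                frame_index=int(rec["frame"]),
                boundary=rec["boundary"],
            )
        )
    out = ContourSet(
        contours=contours,
        reference_frame=int(doc["reference_frame"]),
        es_frame=None if doc.get("es_frame") is None else int(doc["es_frame"]),
        provenance=doc["provenance"],
    )
    if validate:
        out.validate()
    return out


@dataclass
class StrainTable:
    """Tabular strain output: per-frame curves and per-segment signed peaks."""

    curves: pd.DataFrame
    peaks: pd.DataFrame

    def validate(self) -> None:
        if list(self.curves.columns) != CURVES_COLUMNS:
            raise ValidationError("curves table has unexpected columns")
        if list(self.peaks.columns) != PEAKS_COLUMNS:
            raise ValidationError("peaks table has unexpected columns")
        key = ["slice_id", "segment", "frame"]
        if self.curves.duplicated(subset=key).any():
            raise ValidationError("duplicate (slice_id, segment, frame) rows")

    def write(self, path_prefix) -> tuple[Path, Path]:
        prefix = Path(path_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        curves_path = prefix.with_name(prefix.name + "_curves.csv")
        peaks_path = prefix.with_name(prefix.name + "_peaks.csv")
        self.curves.to_csv(curves_path, index=False)
        self.peaks.to_csv(peaks_path, index=False)
        return curves_path, peaks_path

    @classmethod
    def read(cls, path_prefix) -> "StrainTable":
        prefix = Path(path_prefix)
        curves_path = prefix.with_name(prefix.name + "_curves.csv")
        peaks_path = prefix.with_name(prefix.name + "_peaks.csv")
        for p in (curves_path, peaks_path):
            if not p.exists():
                raise SchemaError(f"strain table file not found: {p}")
        curves = pd.read_csv(curves_path)
        peaks = pd.read_csv(peaks_path)
        out = cls(curves=curves, peaks=peaks)
        out.validate()
        return out


def write_strain_tables(table: StrainTable, path_prefix) -> tuple[Path, Path]:
    table.validate()
    return table.write(path_prefix)
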