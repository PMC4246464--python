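"""Agreement statistics between two paired analyses of the same data.

Three complementary summaries are used to compare strain/torsion values from
two processing arms (e.g. full manual contours vs the three-contour
simplification):

* a modified coefficient of variation,
  ``CoV = [sum_i StDev(x_o[i], x_s[i])] / |sum_i (x_o[i] + x_s[i]) / 2| * 100``
  where the two-sample standard deviation of a pair is ``|a - b| / sqrt(2)``
  (N-1 denominator);
* the root-mean-squared error between matched curves,
  ``RMSE = sqrt(sum_i (x_o[i] - x_s[i])^2 / N)``;
* Bland-Altman bias and 95% limits of agreement,
  ``bias = mean(x_s - x_o)``, half-width ``1.96 * SD(x_s - x_o)`` (N-1),
  reported in "bias +/- half-width" form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .io import StrainTable


@dataclass
class PairedMeasures:
    """Matched value sequences from two analyses of the same quantity."""

    x_o: np.ndarray
    x_s: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        self.x_o = np.asarray(self.x_o, dtype=float).ravel()
        self.x_s = np.asarray(self.x_s, dtype=float).ravel()
        if len(self.x_o) != len(self.x_s):
            raise ValidationError("paired sequences must have equal length")
        if len(self.x_o) == 0:
            raise InsufficientDataError("empty paired sequences")

    @property
    def n(self) -> int:
        return len(self.x_o)


@dataclass
class AgreementStats:
    label: str
    n: int
    bias: float
    loa_halfwidth: float
    cov_percent: float
    rmse: float


def _as_pairs(pairs, x_s=None) -> PairedMeasures:
    if isinstance(pairs, PairedMeasures):
        return pairs
    return PairedMeasures(pairs, x_s)


def cov_modified(pairs, x_s=None) -> float:
    """Modified coefficient of variation, percent.

    Numerator: sum over pairs of the two-sample SD ``|a - b| / sqrt(2)``;
    denominator: absolute value of the summed pair means.
    """
    p = _as_pairs(pairs, x_s)
    denom = abs(float(np.sum((p.x_o + p.x_s) / 2.0)))
    if denom == 0.0:
        raise ValidationError("modified CoV undefined: paired means sum to zero")
    num = float(np.sum(np.abs(p.x_o - p.x_s) / math.sqrt(2.0)))
    return 100.0 * num / denom


def rmse_curves(pairs, x_s=None) -> float:
    """Root-mean-squared error between matched sequences (input units)."""
    p = _as_pairs(pairs, x_s)
    return float(np.sqrt(np.mean((p.x_o - p.x_s) ** 2)))


def bland_altman(pairs, x_s=None) -> tuple[float, float]:
    """(bias, loa_halfwidth): mean and 1.96*SD of differences x_s - x_o."""
    p = _as_pairs(pairs, x_s)
    if p.n < 2:
        raise InsufficientDataError("Bland-Altman limits need at least 2 pairs")
    d = p.x_s - p.x_o
    bias = float(np.mean(d))
    halfwidth = 1.96 * float(np.std(d, ddof=1))
    return bias, halfwidth


def _peak_column(table: StrainTable) -> Optional[str]:
    for col in ("peak_Ecc_percent", "peak_Err_percent", "peak_Ell_percent"):
        if table.peaks[col].notna().any():
            return col
    return None


def compare_results(
    a: StrainTable,
    b: StrainTable,
    match_on: tuple[str, ...] = ("slice_id", "segment"),
) -> dict[str, AgreementStats]:
    """Peak and curve agreement between two strain tables.

    Peaks are compared with the modified CoV and Bland-Altman statistics;
    curves with per-segment RMSE, averaged over segments.  Keys present in
    only one table are dropped; callers can detect drops from the returned
    ``n`` values.
    """
    out: dict[str, AgreementStats] = {}
    match_on = list(match_on)

    for col in ("peak_Ecc_percent", "peak_Err_percent", "peak_Ell_percent"):
        pa = a.peaks[match_on + [col]].dropna(subset=[col])
        pb = b.peaks[match_on + [col]].dropna(subset=[col])
        if pa.empty or pb.empty:
            continue
        merged = pa.merge(pb, on=match_on, suffixes=("_o", "_s"))
        if merged.empty:
            raise ValidationError(f"no matching keys between peak tables for {col}")
        pairs = PairedMeasures(
            merged[col + "_o"].to_numpy(), merged[col + "_s"].to_numpy(), label=col
        )
        bias, loa = bland_altman(pairs) if pairs.n >= 2 else (float(pairs.x_s - pairs.x_o), 0.0)
        out[col] = AgreementStats(
            label=col,
            n=pairs.n,
            bias=bias,
            loa_halfwidth=loa,
            cov_percent=cov_modified(pairs),
            rmse=rmse_curves(pairs),
        )

    for col in ("Ecc_percent", "Err_percent", "Ell_percent", "twist_deg"):
        ca = a.curves[match_on + ["frame", col]].dropna(subset=[col])
        cb = b.curves[match_on + ["frame", col]].dropna(subset=[col])
        if ca.empty or cb.empty:
            continue
        merged = ca.merge(cb, on=match_on + ["frame"], suffixes=("_o", "_s"))
        if merged.empty:
            raise ValidationError(f"no matching keys between curve tables for {col}")
        per_seg = []
        for _, grp in merged.groupby(match_on, sort=True):
            per_seg.append(
                rmse_curves(grp[col + "_o"].to_numpy(), grp[col + "_s"].to_numpy())
            )
        out["curve_" + col] = AgreementStats(
            label="curve_" + col,
            n=len(merged),
            bias=float(np.mean(merged[col + "_s"] - merged[col + "_o"])),
            loa_halfwidth=float("nan"),
            cov_percent=float("nan"),
            rmse=float(np.mean(per_seg)),
        )
    if not out:
        raise ValidationError("tables share no comparable measures")
    return out


def stats_to_frame(stats: dict[str, AgreementStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": s.label,
                "n": s.n,
                "bias": s.bias,
                "loa_halfwidth": s.loa_halfwidth,
                "cov_percent": s.cov_percent,
                "rmse": s.rmse,
            }
            for s in stats.values()
        ]
    )
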