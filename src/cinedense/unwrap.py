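"""Seeded quality-guided path-following 2D phase unwrapping.

The unwrapper grows a region outward from seed pixels in descending quality
order (a priority flood).  A newly visited pixel receives its neighbor's
unwrapped value plus the wrapped difference of the two wrapped values, so the
result is congruent to the input modulo 2*pi at every visited pixel.  Seed
pixels keep their wrapped value: they are asserted to be already-unwrapped
phase, which fixes the otherwise arbitrary global 2*pi multiple.

Quality is the negative local variance of wrapped phase differences in a 3x3
window: smooth tissue scores high, pure-noise pixels score very low.  The
same score also serves downstream as a noise detector (pixels whose phase is
"solely noise" separate cleanly from tissue by orders of magnitude in this
variance).

Each frame is unwrapped independently; :func:`plan_seeds` automates the
manual seed-picking step by tracking a set of always-masked pixels through
time (frame-to-frame phase increments are small near the reference) and
choosing, per frame, a high-quality pixel whose true phase provably lies
within (-pi, pi) so the seed contract holds.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import InsufficientDataError, ValidationError
from .io import wrap_phase

QUALITY_SENTINEL = -np.inf

_NEIGHBORS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class UnwrapResult:
    unwrapped: np.ndarray  # radians, NaN where unvisited
    visited: np.ndarray  # bool
    seeds: list[tuple[int, int]]

    @property
    def fully_visited(self) -> bool:
        return bool(self.visited.sum() == np.isfinite(self.unwrapped).sum())


def quality_map(phase: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-pixel quality: negative variance of wrapped in-mask phase
    differences collected over a 3x3 window.  Masked-out pixels get -inf."""
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if phase.shape != mask.shape:
        raise ValidationError("phase and mask shapes differ")
    rows, cols = phase.shape

    vals = np.zeros((rows, cols))
    sq = np.zeros((rows, cols))
    cnt = np.zeros((rows, cols))

    def _accumulate(diff: np.ndarray, valid: np.ndarray, loc) -> None:
        # deposit each difference at its originating pixel, zero elsewhere
        v = np.zeros((rows, cols))
        c = np.zeros((rows, cols))
        v[loc] = np.where(valid, diff, 0.0)
        c[loc] = valid.astype(float)
        vals[:] += v
        sq[:] += v**2
        cnt[:] += c

    dx = wrap_phase(phase[:, 1:] - phase[:, :-1])
    vx = mask[:, 1:] & mask[:, :-1]
    _accumulate(dx, vx, np.s_[:, :-1])
    dy = wrap_phase(phase[1:, :] - phase[:-1, :])
    vy = mask[1:, :] & mask[:-1, :]
    _accumulate(dy, vy, np.s_[:-1, :])

    k = np.ones((3, 3))
    s1 = ndimage.convolve(vals, k, mode="constant")
    s2 = ndimage.convolve(sq, k, mode="constant")
    n = ndimage.convolve(cnt, k, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n > 0, s2 / np.maximum(n, 1) - (s1 / np.maximum(n, 1)) ** 2, 0.0)
    var = np.maximum(var, 0.0)
    quality = -var
    quality[~mask] = QUALITY_SENTINEL
    return quality


def unwrap_region(
    phase: np.ndarray,
    mask: np.ndarray,
    seeds,
    quality: Optional[np.ndarray] = None,
) -> UnwrapResult:
    """Priority-flood unwrapping from seed pixels (row-major tie-break)."""
    phase = np.asarray(phase, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    seeds = [tuple(int(v) for v in s) for s in np.atleast_2d(np.asarray(seeds))]
    if not seeds:
        raise ValidationError("at least one seed required")
    for r, c in seeds:
        if not mask[r, c]:
            raise ValidationError(f"seed ({r}, {c}) outside mask")
    if quality is None:
        quality = quality_map(phase, mask)

    rows, cols = phase.shape
    out = np.full((rows, cols), np.nan)
    visited = np.zeros((rows, cols), dtype=bool)
    heap: list[tuple[float, int, float]] = []
    for r, c in seeds:
        heapq.heappush(heap, (-quality[r, c], r * cols + c, phase[r, c]))
    while heap:
        _, idx, value = heapq.heappop(heap)
        r, c = divmod(idx, cols)
        if visited[r, c]:
            continue
        visited[r, c] = True
        out[r, c] = value
        for dr, dc in _NEIGHBORS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and not visited[nr, nc]:
                nv = value + float(wrap_phase(phase[nr, nc] - phase[r, c]))
                heapq.heappush(heap, (-quality[nr, nc], nr * cols + nc, nv))
    return UnwrapResult(unwrapped=out, visited=visited, seeds=seeds)


def auto_seed(
    phase: np.ndarray,
    mask: np.ndarray,
    quality: Optional[np.ndarray] = None,
) -> list[tuple[int, int]]:
    """One seed per connected mask component.

    Candidates are ranked first by small wrapped-phase magnitude (binned, so
    near-zero-displacement pixels win), then by quality, then row-major.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask")
    if quality is None:
        quality = quality_map(phase, mask)
    labels, n_comp = ndimage.label(mask)
    seeds = []
    absphase = np.abs(wrap_phase(phase))
    for comp in range(1, n_comp + 1):
        rr, cc = np.nonzero(labels == comp)
        bins = np.round(absphase[rr, cc] / 0.25)
        order = np.lexsort((rr * mask.shape[1] + cc, -quality[rr, cc], bins))
        k = order[0]
        seeds.append((int(rr[k]), int(cc[k])))
    return seeds


def plan_seeds(
    phase_stack: np.ndarray,
    masks: np.ndarray,
    margin_rad: float = 0.5,
    qualities: Optional[list[np.ndarray]] = None,
) -> list[Optional[list[tuple[int, int]]]]:
    """Choose one branch-safe seed per frame for a whole cine stack.

    Pixels masked on every frame are tracked through time with a 1D running
    wrap-correction (valid while frame-to-frame increments stay below pi);
    for each frame, the highest-quality tracked pixel whose accumulated phase
    lies safely inside (-pi, pi) becomes the seed, so keeping its wrapped
    value is correct.  Frames without a safe tracked pixel fall back to
    :func:`auto_seed`.
    """
    phase_stack = np.asarray(phase_stack, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    F = phase_stack.shape[0]
    if qualities is None:
        qualities = [quality_map(phase_stack[f], masks[f]) for f in range(F)]
    cols = phase_stack.shape[2]
    seeds: list[Optional[list[tuple[int, int]]]] = [None] * F

    always = masks.all(axis=0)
    if always.any():
        rr, cc = np.nonzero(always)
        ph = phase_stack[:, rr, cc]  # (F, P)
        temp = np.empty_like(ph)
        temp[0] = wrap_phase(ph[0])
        for f in range(1, F):
            temp[f] = temp[f - 1] + wrap_phase(ph[f] - ph[f - 1])
        for f in range(F):
            safe = np.abs(temp[f]) < (np.pi - margin_rad)
            if safe.any():
                q = qualities[f][rr, cc]
                order = np.lexsort((rr * cols + cc, -q))
                for k in order:
                    if safe[k]:
                        seeds[f] = [(int(rr[k]), int(cc[k]))]
                        break
    for f in range(F):
        if seeds[f] is None and masks[f].any():
            seeds[f] = auto_seed(phase_stack[f], masks[f], qualities[f])
    if any(s is None for s in seeds):
        raise InsufficientDataError("a frame has an empty mask; cannot seed")
    return seeds
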