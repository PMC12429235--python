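"""Fractal dimension of grayscale height maps by Integer-Ratio Differential Box Counting.

A topological surface in mm is quantized into an integer height map at one
gray level per millimetre. Differential box counting (DBC) covers the map
with an ``s x s`` grid of cells; over each cell the spanned gray range is
measured and the number of stacked boxes of height ``h`` needed to cover it
is counted, ``N(s)`` being the weighted cell total. The *integer-ratio*
device lets ``s`` be any integer: edge cells that hang over the image border
contribute with a weight equal to the in-image fraction of their footprint,
so no pixels are discarded and no box size is excluded. The fractal
dimension ``D`` is the slope of ``log N(s)`` against ``log(1/s)``; a flat
surface gives exactly ``D = 2`` and a space-filling one approaches ``D = 3``.

Surface roughness is reported as ``SR = (D - 2) * 100``: the percentage of
the measurement box's height dimension occupied beyond a flat surface, with
SR = 0 anchored at a perfectly flat map and SR = 100 at a space-filling one.

Two numerical choices keep the estimate well behaved on the low-relief maps
the trachea pipeline produces (see :func:`_box_height_ratio` and
:func:`irdbc_counts`): the box-height normalization floors the dynamic range
at ``GRAY_RANGE_FLOOR`` levels, and cells occupy a fractional number of
boxes (floored at one) instead of a ceil-rounded integer. All cell counts
use exact integer arithmetic until a single final division, so the
optimized counter and the brute-force oracle agree exactly, not just to
floating-point tolerance. A constant cell always contributes exactly one
box, so a flat map yields ``N(s) = (M/s)^2`` and ``D = 2`` identically.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import InsufficientScalesError

log = logging.getLogger(__name__)


@dataclass
class HeightMap:
    """2D integer height map; one gray level corresponds to ``mm_per_gray`` mm.

    Pixels are normalized on construction so the minimum maps to gray level 0.
    """

    pixels: np.ndarray
    mm_per_gray: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"height map must be 2D, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("height map must be non-empty")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("height map pixels must be integers; quantize first")
        self.pixels = (px - px.min()).astype(np.int64)

    @property
    def dims(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_gray(self) -> int:
        """Number of gray levels spanned (max - min + 1); >= 1."""
        return int(self.pixels.max()) + 1


def quantize_heights(heights_mm: np.ndarray, mm_per_gray: float = 1.0) -> HeightMap:
    """Shift heights so the minimum is zero and round half-up to gray levels."""
    h = np.asarray(heights_mm, dtype=float)
    shifted = (h - h.min()) / mm_per_gray
    levels = np.floor(shifted + 0.5).astype(np.int64)  # round-half-up, deterministic
    return HeightMap(pixels=levels, mm_per_gray=mm_per_gray)


def to_heightmap(surface, component: str) -> HeightMap:
    """Quantize one component of a :class:`~trachea_sr.surface.RadialSurface`.

    ``component`` is one of ``"shape"``, ``"curvature"``, ``"total"``. Before
    quantization the unrolled surface is resampled along theta so one pixel
    subtends the same arc length (at the mean radius) as one axial step:
    the counting grid is then isotropic in physical mm, and the box counts do
    not depend on how many rays were cast during sampling.
    """
    heights = np.asarray(surface.component(component), dtype=float)  # raises if not populated
    dz = float(surface.z[1] - surface.z[0]) if surface.z.size > 1 else 1.0
    mean_radius = float(surface.r_total.mean())
    n_cols = max(16, int(round(2.0 * np.pi * mean_radius / dz)))
    theta_map = np.linspace(0.0, 2.0 * np.pi, n_cols, endpoint=False)
    theta_ext = np.append(surface.theta, 2.0 * np.pi)
    heights_ext = np.vstack([heights, heights[:1]])
    resampled = np.empty((n_cols, heights.shape[1]))
    for j in range(heights.shape[1]):
        resampled[:, j] = np.interp(theta_map, theta_ext, heights_ext[:, j])
    return quantize_heights(resampled, mm_per_gray=1.0)


def default_box_sizes(dims: tuple[int, int]) -> list[int]:
    """Every integer box size in [min(dims)//8, min(dims)//4].

    The top keeps at least 4 cells per axis. The bottom excludes the fine
    scales where per-cell gray ranges collapse to a level or two and the
    1-mm quantization floor drags the local log-log slope toward 2; on
    fractional-Brownian oracle surfaces the octave below the largest
    admissible box recovers the theoretical dimension 3 - H with the least
    bias.
    """
    top = min(dims) // 4
    bottom = max(2, min(dims) // 8)
    return list(range(bottom, top + 1))


def _check_box_size(s: int, dims: tuple[int, int]) -> None:
    if s < 2 or s > min(dims) // 2:
        raise ValueError(f"box size {s} out of range [2, {min(dims) // 2}] for dims {dims}")


GRAY_RANGE_FLOOR = 24  # minimum dynamic range (levels) used in box-height scaling


def _box_height_ratio(s: int, n_gray: int, min_dim: int) -> tuple[int, int]:
    """Box height ``h = s * max(n_gray, GRAY_RANGE_FLOOR) / min_dim`` as an
    exact rational (num, den).

    Two guards keep the height scaling meaningful on maps that span only a
    few gray levels (surfaces whose relief is of the order of the 1-mm
    quantization step):

    * the dynamic-range normalization is floored at ``GRAY_RANGE_FLOOR``
      levels so the box height stays proportional to the box edge instead of
      collapsing to a constant, which would destroy the scaling exponent.
      With the default ladder starting at ``min_dim / 8`` the floored height
      is three gray levels at the smallest fitted scale: tall enough that
      counts are not dominated by one-level integer-straddle artifacts
      (which saturate the estimate on any noisy map), while low-relief
      texture still registers through cells whose gray range crosses a box
      boundary, so the roughness response stays monotone in texture
      amplitude. Maps whose range exceeds the floor are unaffected.
    * the height is clamped to >= 1 gray level, since a box shorter than the
      quantization step would resolve structure the height map cannot
      contain and inflates counts on flat cells.
    """
    num, den = s * max(n_gray, GRAY_RANGE_FLOOR), min_dim
    if num < den:
        num = den
    return num, den


def irdbc_counts(hmap: HeightMap, box_sizes: list[int] | None = None) -> tuple[list[int], list[float]]:
    """Integer-ratio differential box counts N(s) for each box size.

    Returns ``(box_sizes, counts)``. Partial cells at the right/bottom edges
    are weighted by the fraction of the cell footprint inside the image.
    """
    px = hmap.pixels
    m0, m1 = px.shape
    if box_sizes is None:
        box_sizes = default_box_sizes(hmap.dims)
    n_gray = hmap.n_gray
    counts: list[float] = []
    for s in box_sizes:
        _check_box_size(s, hmap.dims)
        nr, nc = -(-m0 // s), -(-m1 // s)
        pad0, pad1 = nr * s - m0, nc * s - m1
        # pad values outside the image must never win the max/min reductions
        mx = np.pad(px, ((0, pad0), (0, pad1)), constant_values=-1)
        mn = np.pad(px, ((0, pad0), (0, pad1)), constant_values=n_gray + 1)
        g_max = mx.reshape(nr, s, nc, s).max(axis=(1, 3))
        g_min = mn.reshape(nr, s, nc, s).min(axis=(1, 3))
        num, den = _box_height_ratio(s, n_gray, min(m0, m1))
        # differential count, continuous relaxation: a cell spanning the gray
        # interval [g_min, g_max + 1) occupies (g_max - g_min + 1) / h boxes,
        # floored at one box. Fractional box occupancy mirrors the fractional
        # footprint weights of the edge cells and removes the integer
        # saturation steps of ceil-counting, which would otherwise make the
        # estimate jump with box-stack alignment on low-relief maps. All
        # arithmetic is integer until the final division, so the brute-force
        # oracle can match bit-for-bit.
        p = np.maximum((g_max - g_min + 1) * den, num)  # n = p / num boxes
        rows_in = np.full(nr, s, dtype=np.int64)
        rows_in[-1] = m0 - (nr - 1) * s
        cols_in = np.full(nc, s, dtype=np.int64)
        cols_in[-1] = m1 - (nc - 1) * s
        numerator = int((p * np.outer(rows_in, cols_in)).sum())
        counts.append(numerator / (num * s * s))
    return list(box_sizes), counts


def brute_force_box_count(hmap: HeightMap, s: int) -> float:
    """Independent oracle: walk every cell with naive slicing and exact
    rational arithmetic (no padding, reshaping or vectorized reductions).

    Each cell spanning the gray interval ``[g_min, g_max + 1)`` occupies
    ``max(1, (g_max - g_min + 1) / h)`` boxes of height ``h``, weighted by
    the in-image fraction of its footprint. Intended for small maps
    (<= 64 x 64).
    """
    px = hmap.pixels
    m0, m1 = px.shape
    _check_box_size(s, hmap.dims)
    num, den = _box_height_ratio(s, hmap.n_gray, min(m0, m1))
    h = Fraction(num, den)
    total = Fraction(0)
    for r0 in range(0, m0, s):
        for c0 in range(0, m1, s):
            cell = px[r0:r0 + s, c0:c0 + s]
            g_min, g_max = int(cell.min()), int(cell.max())
            boxes = max(Fraction(1), Fraction(g_max - g_min + 1, 1) / h)
            weight = Fraction(cell.shape[0] * cell.shape[1], s * s)
            total += boxes * weight
    return float(total)


@dataclass
class FractalResult:
    """Box-counting scaling fit: D, goodness of fit, and the SR percentage."""

    box_sizes: list[int]
    counts: list[float]
    D: float
    fit_r2: float
    SR: float
    D_raw: float = math.nan
    clamped: bool = False
    component: str = ""
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "D": self.D,
            "D_raw": self.D_raw,
            "fit_r2": self.fit_r2,
            "SR": self.SR,
            "clamped": self.clamped,
            "box_sizes": list(self.box_sizes),
            "counts": list(self.counts),
            "notes": list(self.notes),
        }


def fractal_dimension(box_sizes, counts) -> tuple[float, float]:
    """OLS slope of log N(s) on log(1/s); returns (D clamped to [2, 3], R^2)."""
    s = np.asarray(box_sizes, dtype=float)
    n = np.asarray(counts, dtype=float)
    if s.size < 4 or np.any(n <= 0):
        raise InsufficientScalesError(
            f"need >= 4 box sizes with positive counts, got {s.size}"
        )
    x = np.log(1.0 / s)
    y = np.log(n)
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    d = float(np.clip(slope, 2.0, 3.0))
    if d != slope:
        log.info("fractal dimension %.4f clamped into [2, 3]", slope)
    return d, float(r2)


def dimension_to_sr(D: float) -> float:
    """Map a fractal dimension to a surface-roughness percentage, SR = (D - 2) * 100."""
    if not (2.0 - 1e-9 <= D <= 3.0 + 1e-9):
        raise ValueError(f"fractal dimension {D} outside [2, 3]; clamp before converting")
    return float(np.clip((D - 2.0) * 100.0, 0.0, 100.0))


def analyze_heightmap(hmap: HeightMap, box_sizes: list[int] | None = None,
                      component: str = "") -> FractalResult:
    """Full box-counting analysis of one height map.

    A single-gray-level map is the flat-surface limit and short-circuits to
    D = 2, SR = 0 (counts are still reported for diagnostics).
    """
    sizes, counts = irdbc_counts(hmap, box_sizes)
    notes: list[str] = []
    if hmap.n_gray == 1:
        return FractalResult(sizes, counts, 2.0, 1.0, 0.0, D_raw=2.0,
                             component=component, notes=["flat map (n_gray=1)"])
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, float)),
                       np.log(np.asarray(counts, float)), 1)[0]
    d, r2 = fractal_dimension(sizes, counts)
    clamped = not math.isclose(d, slope, rel_tol=0, abs_tol=1e-12)
    if clamped:
        notes.append(f"D clamped from {slope:.4f}")
    return FractalResult(sizes, counts, d, r2, dimension_to_sr(d),
                         D_raw=float(slope), clamped=clamped,
                         component=component, notes=notes)
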