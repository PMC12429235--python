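"""Synthetic airway phantoms with known ground truth.

The generator voxelizes a roughly vertical tubular lumen that mimics a
trachea on inspiratory CT: base radius ~8-12 mm, elliptical cross-sections
with a controllable coronal/sagittal ratio (the tracheal-index ground truth),
an optional sinusoidal bow of the centerline (global curvature), multi-scale
radial wall texture (periodic fractional-Brownian perturbation with
controllable Hurst exponent and RMS amplitude), and an optional distal
bifurcation whose last single-lumen slice is the carina ground truth.

Every stage of the measurement pipeline is testable against these phantoms
without clinical data: the construction parameters *are* the expected
measurements. All randomness flows through explicit seeds.

Default spacing is 0.6 x 0.6 x 1.0 mm, matching a 1 mm slice-thickness
inspiratory acquisition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ResolutionError
from .fractal import HeightMap, quantize_heights
from .mask_io import VoxelMask

DEFAULT_SPACING = (0.6, 0.6, 1.0)

# Children of the bifurcation: radius and initial lateral offset as fractions
# of the parent radius. Offset > radius fraction so the two child lumens are
# disjoint in-plane immediately below the split, while still overlapping the
# parent footprint in 3D (keeps the tree 26-connected across the carina).
_CHILD_RADIUS_FRAC = 0.55
_CHILD_OFFSET_FRAC = 0.65


@dataclass(frozen=True)
class FbmPerturbation:
    """Fractional-Brownian radial texture: PSD ~ f^-(2H+2), periodic in theta."""

    hurst: float
    amplitude_rms: float  # mm
    seed: int = 0
    n_theta: int = 256  # theta resolution of the synthesized field

    def __post_init__(self) -> None:
        if not (0.0 < self.hurst < 1.0):
            raise ValueError(f"Hurst exponent must be in (0, 1), got {self.hurst}")
        if self.amplitude_rms < 0:
            raise ValueError("amplitude_rms must be >= 0")


@dataclass(frozen=True)
class SinusoidPerturbation:
    """Deterministic radial ripple A*cos(k_theta * theta)*cos(2*pi*k_z*z/L)."""

    amplitude: float  # mm
    n_theta_cycles: int
    n_z_cycles: int = 0  # 0 => constant along z


@dataclass(frozen=True)
class Bifurcation:
    """Distal split of the lumen; z_split_mm measured from the tube bottom."""

    z_split_mm: float
    branch_angle_deg: float = 30.0


@dataclass(frozen=True)
class TubeSpec:
    """Parametric description of a tubular airway phantom.

    ``cross_section_ratio`` is the coronal/sagittal diameter ratio d_c/d_s,
    either constant or a ``(top, bottom)`` pair varied linearly along z.
    The elliptical cross-section keeps the geometric mean radius equal to
    ``base_radius``. The centerline is straight or a sinusoidal bow in the
    coronal (x) direction.
    """

    base_radius: float = 9.0  # mm
    length: float = 100.0  # mm
    cross_section_ratio: float | tuple[float, float] = 1.0
    bow_amplitude_mm: float = 0.0
    bow_wavelength_mm: float | None = None  # default: 2 * length (single arc)
    perturbation: FbmPerturbation | SinusoidPerturbation | None = None
    bifurcation: Bifurcation | None = None

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.length <= 0:
            raise ValueError("base_radius and length must be positive")
        for r in self._ratio_pair():
            if not (0.0 < r <= 1.5):
                raise ValueError(f"cross_section_ratio must be in (0, 1.5], got {r}")
        if self.bifurcation is not None and not (0 < self.bifurcation.z_split_mm < self.length):
            raise ValueError("bifurcation z_split_mm must lie inside the tube")

    def _ratio_pair(self) -> tuple[float, float]:
        r = self.cross_section_ratio
        if isinstance(r, (tuple, list)):
            return float(r[0]), float(r[1])
        return float(r), float(r)

    def ratio_at(self, z_mm: np.ndarray | float) -> np.ndarray | float:
        """d_c/d_s at height z (mm from the tube bottom); linear top<->bottom."""
        top, bottom = self._ratio_pair()
        return bottom + (top - bottom) * np.asarray(z_mm) / self.length

    def bow_at(self, z_mm: np.ndarray | float) -> np.ndarray | float:
        """Coronal centerline displacement at height z (mm)."""
        if self.bow_amplitude_mm == 0:
            return np.zeros_like(np.asarray(z_mm, dtype=float))
        lam = self.bow_wavelength_mm or 2.0 * self.length
        return self.bow_amplitude_mm * np.sin(2.0 * np.pi * np.asarray(z_mm) / lam)

    # -- plain-text round trip ------------------------------------------------
    def to_config(self, path) -> Path:
        """Serialize to a YAML file; regenerable bit-exactly given the seed."""
        d = asdict(self)
        d["perturbation_kind"] = type(self.perturbation).__name__ if self.perturbation else "none"
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_config(cls, path) -> "TubeSpec":
        d = yaml.safe_load(Path(path).read_text())
        kind = d.pop("perturbation_kind", "none")
        pert = d.pop("perturbation", None)
        if kind == "FbmPerturbation":
            d["perturbation"] = FbmPerturbation(**pert)
        elif kind == "SinusoidPerturbation":
            d["perturbation"] = SinusoidPerturbation(**pert)
        bif = d.pop("bifurcation", None)
        if bif is not None:
            d["bifurcation"] = Bifurcation(**bif)
        ratio = d.get("cross_section_ratio")
        if isinstance(ratio, list):
            d["cross_section_ratio"] = tuple(ratio)
        return cls(**d)


@dataclass
class PhantomTruth:
    """Construction-time ground truth recorded alongside a voxelized phantom."""

    carina_index: int | None
    z_slices: np.ndarray = field(repr=False)  # mm from tube bottom, per slice
    ratios: np.ndarray = field(repr=False)  # d_c/d_s per slice
    perturbation_rms: float = 0.0
    field_theta: np.ndarray | None = field(default=None, repr=False)
    field_values: np.ndarray | None = field(default=None, repr=False)  # (n_theta, n_z)
    spec: TubeSpec | None = None


def make_fbm_field(n_theta: int, n_z: int, hurst: float, amplitude_rms: float,
                   seed: int) -> np.ndarray:
    """Periodic-in-theta fractional-Brownian height field, shape (n_theta, n_z), in mm.

    Spectral synthesis: Gaussian white noise filtered so the power spectral
    density falls as ``f^-(2H+2)``, giving a surface of theoretical fractal
    dimension ``3 - H``. The field is synthesized on a doubled z domain and
    cropped, so the returned field does not wrap in z while remaining exactly
    periodic in theta (the unrolled cylinder direction). Zero mean, scaled to
    the requested RMS. Deterministic for a fixed seed.
    """
    if n_theta < 16 or n_z < 16:
        raise ValueError("n_theta and n_z must be >= 16")
    if not (0.0 < hurst < 1.0):
        raise ValueError(f"Hurst exponent must be in (0, 1), got {hurst}")
    if amplitude_rms < 0:
        raise ValueError("amplitude_rms must be >= 0")
    if amplitude_rms == 0:
        return np.zeros((n_theta, n_z))
    rng = np.random.default_rng(seed)
    nz2 = 2 * n_z
    white = rng.standard_normal((n_theta, nz2))
    f_theta = np.fft.fftfreq(n_theta)[:, None]
    f_z = np.fft.fftfreq(nz2)[None, :]
    freq = np.hypot(f_theta, f_z)
    amp = np.zeros_like(freq)
    nonzero = freq > 0
    amp[nonzero] = freq[nonzero] ** (-(hurst + 1.0))
    spectrum = np.fft.fft2(white) * amp
    fld = np.real(np.fft.ifft2(spectrum))[:, :n_z]
    fld -= fld.mean()
    rms = np.sqrt(np.mean(fld ** 2))
    return fld * (amplitude_rms / rms)


def _ellipse_radius(theta: np.ndarray, r0: float, ratio: float) -> np.ndarray:
    """Polar-from-center radius of an ellipse with d_c/d_s = ratio, geo-mean r0."""
    a = r0 * math.sqrt(ratio)  # coronal (x) semi-axis
    b = r0 / math.sqrt(ratio)  # sagittal (y) semi-axis
    return a * b / np.hypot(b * np.cos(theta), a * np.sin(theta))


def make_tube_mask(spec: TubeSpec,
                   spacing: tuple[float, float, float] = DEFAULT_SPACING
                   ) -> tuple[VoxelMask, PhantomTruth]:
    """Voxelize a tube phantom; returns the mask and its ground truth.

    A voxel is foreground when its center lies within the perturbed radial
    boundary ``r(theta, z) = e(theta; ratio(z)) + p(theta, z)`` around the
    centerline, or inside one of the two child tubes below the bifurcation.
    """
    sx, sy, sz = spacing
    if 2.0 * spec.base_radius / max(sx, sy) < 8.0:
        raise ResolutionError(
            f"spacing {spacing} resolves the {2 * spec.base_radius:.1f} mm diameter "
            "with fewer than 8 voxels"
        )
    nz = int(round(spec.length / sz))
    z_slices = (np.arange(nz) + 0.5) * sz

    # perturbation field sampled on (field_theta, slice) lattice
    pert = spec.perturbation
    if isinstance(pert, FbmPerturbation) and pert.amplitude_rms > 0:
        f_theta = np.linspace(0, 2 * np.pi, pert.n_theta, endpoint=False)
        f_values = make_fbm_field(pert.n_theta, nz, pert.hurst, pert.amplitude_rms, pert.seed)
        # wall texture only: the k_theta = 0 mode is per-slice caliber change
        # and k_theta = +-1 is centerline wander, both of which have their own
        # controls (cross_section_ratio, bow); project them out and rescale
        spec_t = np.fft.fft(f_values, axis=0)
        spec_t[[0, 1, -1], :] = 0.0
        f_values = np.real(np.fft.ifft(spec_t, axis=0))
        f_values *= pert.amplitude_rms / np.sqrt(np.mean(f_values ** 2))
        pert_rms = pert.amplitude_rms
    elif isinstance(pert, SinusoidPerturbation):
        f_theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        axial = np.cos(2 * np.pi * pert.n_z_cycles * z_slices / spec.length)
        f_values = pert.amplitude * np.cos(pert.n_theta_cycles * f_theta)[:, None] * axial[None, :]
        pert_rms = float(np.sqrt(np.mean(f_values ** 2)))
    else:
        f_theta, f_values, pert_rms = None, None, 0.0

    # lateral grid extent: ellipse + texture + bow + bifurcation excursion
    top_r, bottom_r = spec._ratio_pair()
    rmax = spec.base_radius / math.sqrt(min(top_r, bottom_r, 1.0))
    margin = 4.0 * pert_rms + abs(spec.bow_amplitude_mm)
    half_x = rmax + margin
    half_y = rmax + margin
    r0 = spec.base_radius
    if spec.bifurcation is not None:
        bif = spec.bifurcation
        reach = (_CHILD_OFFSET_FRAC * r0 + _CHILD_RADIUS_FRAC * r0
                 + math.tan(math.radians(bif.branch_angle_deg)) * bif.z_split_mm)
        half_x = max(half_x, reach)
    nx = 2 * int(math.ceil(half_x / sx)) + 9
    ny = 2 * int(math.ceil(half_y / sy)) + 9
    cx = (nx - 1) / 2.0 * sx
    cy = (ny - 1) / 2.0 * sy

    xs = np.arange(nx)[:, None] * sx
    ys = np.arange(ny)[None, :] * sy
    data = np.zeros((nx, ny, nz), dtype=np.uint8)
    ratios = np.asarray(spec.ratio_at(z_slices), dtype=float)
    carina_index: int | None = None
    if spec.bifurcation is not None:
        # last single-lumen slice = lowest slice center at/above the split plane
        carina_index = int(np.argmax(z_slices >= spec.bifurcation.z_split_mm))

    for k, z in enumerate(z_slices):
        if spec.bifurcation is not None and z < spec.bifurcation.z_split_mm:
            depth = spec.bifurcation.z_split_mm - z
            off = (_CHILD_OFFSET_FRAC * r0
                   + math.tan(math.radians(spec.bifurcation.branch_angle_deg)) * depth)
            rc = _CHILD_RADIUS_FRAC * r0
            left = np.hypot(xs - (cx - off), ys - cy) <= rc
            right = np.hypot(xs - (cx + off), ys - cy) <= rc
            data[:, :, k] = (left | right).astype(np.uint8)
            continue
        bx = cx + float(spec.bow_at(z))
        dx = xs - bx
        dy = ys - cy
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        rho = np.hypot(dx, dy)
        boundary = _ellipse_radius(theta, r0, float(ratios[k]))
        if f_values is not None:
            # periodic linear interpolation of the texture field in theta
            col = f_values[:, k]
            boundary = boundary + np.interp(
                theta, np.append(f_theta, 2 * np.pi), np.append(col, col[0])
            )
        data[:, :, k] = (rho <= boundary).astype(np.uint8)

    mask = VoxelMask(data=data, spacing=spacing)
    truth = PhantomTruth(
        carina_index=carina_index,
        z_slices=z_slices,
        ratios=ratios,
        perturbation_rms=pert_rms,
        field_theta=f_theta,
        field_values=f_values,
        spec=spec,
    )
    return mask, truth


def trachea_phantom(amplitude_rms: float = 0.0, hurst: float = 0.5,
                    ratio: float | tuple[float, float] = 1.0, seed: int = 0,
                    base_radius: float = 9.0, length: float = 110.0,
                    z_split_mm: float = 30.0) -> TubeSpec:
    """Convenience spec: a trachea-like tube with a distal bifurcation."""
    pert = FbmPerturbation(hurst, amplitude_rms, seed) if amplitude_rms > 0 else None
    return TubeSpec(
        base_radius=base_radius,
        length=length,
        cross_section_ratio=ratio,
        perturbation=pert,
        bifurcation=Bifurcation(z_split_mm=z_split_mm),
    )


def make_test_heightmap(kind: str, **params) -> HeightMap:
    """Small integer height maps with analytically known box-count behavior.

    Kinds: ``constant`` (shape), ``ramp`` (shape, n_gray), ``checkerboard``
    (shape, n_gray), ``fbm`` (shape, hurst, amplitude_rms, seed).
    """
    shape = params.pop("shape", (64, 64))
    if kind == "constant":
        params.pop("level", None)
        hm = HeightMap(np.zeros(shape, dtype=np.int64))
    elif kind == "ramp":
        n_gray = int(params.pop("n_gray", 8))
        cols = np.floor(np.arange(shape[1]) * n_gray / shape[1]).astype(np.int64)
        hm = HeightMap(np.broadcast_to(cols, shape).copy())
    elif kind == "checkerboard":
        n_gray = int(params.pop("n_gray", 2))
        ii, jj = np.indices(shape)
        hm = HeightMap(((ii + jj) % 2 * (n_gray - 1)).astype(np.int64))
    elif kind == "fbm":
        hurst = float(params.pop("hurst"))
        amplitude_rms = float(params.pop("amplitude_rms", 16.0))
        seed = int(params.pop("seed", 0))
        fld = make_fbm_field(shape[0], shape[1], hurst, amplitude_rms, seed)
        hm = quantize_heights(fld)
    else:
        raise ValueError(f"unknown height-map kind {kind!r}")
    if params:
        raise ValueError(f"unused parameters for kind {kind!r}: {sorted(params)}")
    return hm
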