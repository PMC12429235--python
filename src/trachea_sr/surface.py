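"""Cylindrical parameterization of the trachea lumen and its decomposition.

The lumen boundary is mapped to a 2D radius grid ``r(theta, z)`` by casting
rays from the per-slice centroid and locating the sub-voxel position where
the bilinearly interpolated mask crosses 0.5 (first crossing from inside
out, which keeps the unrolled surface single-valued). Rays are cast from the
per-slice centroid for robustness, then each boundary curve is re-expressed
as a radius about the fixed segment-mean axis so that bending of the airway
contributes to the total surface. Radii are resampled to a uniform axial
spacing so the millimetre-scale quantization downstream is independent of
the acquisition slice thickness.

The total radius field is then split additively into three parts::

    r_total(theta, z) = r_mean(z) + r_curvature(theta, z) + r_shape(theta, z)

* ``r_curvature`` - the low-frequency surface induced by global geometry:
  the projection of the per-slice centroid drift onto the ray direction
  (bending of the airway axis) plus the smoothed axial trend of the mean
  radius (gradual widening/narrowing).
* ``r_shape`` - the residual wall texture, with zero mean over theta at
  every slice by construction.
* ``r_mean`` - the per-slice baseline that makes the identity exact.

theta = 0 points along +x (patient left) and increases counter-clockwise
viewed from superior; z = 0 is the carina slice and grows superiorly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateSliceError
from .extraction import TracheaSegment

log = logging.getLogger(__name__)


@dataclass
class RadialSurface:
    """Radius grid r(theta_i, z_j) in mm with its additive decomposition."""

    theta: np.ndarray = field(repr=False)  # (n_theta,) radians in [0, 2pi)
    z: np.ndarray = field(repr=False)  # (n_z,) mm from the carina slice
    r_total: np.ndarray = field(repr=False)  # (n_theta, n_z) mm, about axis_center
    centroids: np.ndarray = field(repr=False)  # (n_z, 2) per-slice centroid, mm
    axis_center: tuple[float, float] = (0.0, 0.0)  # segment-mean centroid, mm
    r_shape: np.ndarray | None = field(default=None, repr=False)
    r_curvature: np.ndarray | None = field(default=None, repr=False)
    r_mean: np.ndarray | None = field(default=None, repr=False)  # (n_z,)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def n_z(self) -> int:
        return self.z.size

    def component(self, name: str) -> np.ndarray:
        """Return the requested surface component in mm; raises if unpopulated."""
        if name == "total":
            return self.r_total
        if name in ("shape", "curvature"):
            arr = self.r_shape if name == "shape" else self.r_curvature
            if arr is None:
                raise ValueError(f"component {name!r} not populated; call decompose() first")
            return arr
        raise ValueError(f"unknown component {name!r}; expected shape|curvature|total")

    def to_table(self):
        """Long-format DataFrame with theta, z and all populated components."""
        import pandas as pd

        tt, zz = np.meshgrid(self.theta, self.z, indexing="ij")
        cols = {"theta": tt.ravel(), "z_mm": zz.ravel(), "r_total": self.r_total.ravel()}
        if self.r_shape is not None:
            cols["r_shape"] = self.r_shape.ravel()
        if self.r_curvature is not None:
            cols["r_curvature"] = self.r_curvature.ravel()
        return pd.DataFrame(cols)


def _sample_slice(sl: np.ndarray, spacing: tuple[float, float], theta: np.ndarray,
                  max_fail_frac: float, slice_id: int, warnings_out: list[str]
                  ) -> tuple[np.ndarray, tuple[float, float], tuple[float, float]]:
    """Radii along each ray for one slice; returns (radii_mm, origin_mm, centroid_mm).

    Rays start at the centroid; when a strongly non-convex cross-section puts
    the centroid outside the lumen, the interior point farthest from the
    boundary (distance-transform maximum) is used instead. The centroid is
    still reported for the centroid-drift decomposition.
    """
    sx, sy = spacing
    cy_idx = ndimage.center_of_mass(sl)
    cx_mm, cy_mm = cy_idx[0] * sx, cy_idx[1] * sy
    inside = ndimage.map_coordinates(sl.astype(np.float32),
                                     [[cx_mm / sx], [cy_mm / sy]], order=1)[0]
    if inside < 0.5:
        edt = ndimage.distance_transform_edt(sl, sampling=(sx, sy))
        ox_idx, oy_idx = np.unravel_index(int(np.argmax(edt)), sl.shape)
        ox_mm, oy_mm = ox_idx * sx, oy_idx * sy
        warnings_out.append(
            f"slice {slice_id}: centroid outside lumen, rays cast from "
            "distance-transform maximum")
    else:
        ox_mm, oy_mm = cx_mm, cy_mm
    # march outward in sub-voxel steps; boundary = first 0.5-crossing
    dr = 0.25 * min(sx, sy)
    r_max = 1.25 * max(sl.shape[0] * sx, sl.shape[1] * sy) / 2.0
    steps = np.arange(0.0, r_max, dr)
    xs = (ox_mm + np.outer(np.cos(theta), steps)) / sx
    ys = (oy_mm + np.outer(np.sin(theta), steps)) / sy
    vals = ndimage.map_coordinates(sl.astype(np.float32), [xs, ys], order=1,
                                   mode="constant", cval=0.0)
    inside = vals >= 0.5
    radii = np.full(theta.size, np.nan)
    first_out = np.argmax(~inside, axis=1)  # first sub-threshold step per ray
    started_inside = inside[:, 0]
    ok = started_inside & (first_out > 0)
    if ok.any():
        i = first_out[ok]
        v0 = vals[ok, i - 1]
        v1 = vals[ok, i]
        frac = np.where(v0 > v1, (v0 - 0.5) / (v0 - v1), 0.0)
        radii[ok] = steps[i - 1] + frac * dr
    # audit rays that leave and re-enter the lumen (non-star-shaped slice)
    ever_out = np.logical_or.accumulate(~inside, axis=1)
    n_reenter = int(np.count_nonzero((inside & ever_out).any(axis=1)))
    if n_reenter:
        warnings_out.append(f"slice {slice_id}: {n_reenter} non-star-shaped rays (first crossing used)")

    failed = np.isnan(radii)
    if failed.mean() > max_fail_frac:
        raise DegenerateSliceError(
            f"slice {slice_id}: {failed.sum()}/{theta.size} rays failed"
        )
    if failed.any():
        good = ~failed
        # circular linear interpolation over theta
        th_ext = np.concatenate([theta[good] - 2 * np.pi, theta[good], theta[good] + 2 * np.pi])
        r_ext = np.tile(radii[good], 3)
        radii[failed] = np.interp(theta[failed], th_ext, r_ext)
        warnings_out.append(f"slice {slice_id}: {int(failed.sum())} failed rays interpolated")
    return radii, (ox_mm, oy_mm), (cx_mm, cy_mm)


def radial_sample(segment: TracheaSegment, n_theta: int = 360, dz_mm: float = 1.0,
                  max_fail_frac: float = 0.02) -> RadialSurface:
    """Map the lumen boundary of every analyzed slice to a radius grid.

    Per slice: centroid -> ``n_theta`` rays -> sub-voxel 0.5-crossing of the
    bilinear mask interpolation. Isolated failed rays (< ``max_fail_frac`` of
    a slice) are filled by circular interpolation in theta; worse slices
    raise :class:`DegenerateSliceError`. The stacked radii and centroids are
    resampled along z to a uniform ``dz_mm`` lattice by linear interpolation.
    """
    sx, sy, sz = segment.mask.spacing
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    nz = segment.mask.data.shape[2]
    warnings_out: list[str] = []
    radii = np.empty((n_theta, nz))
    origins = np.empty((nz, 2))
    cents = np.empty((nz, 2))
    for k in range(nz):
        sl = segment.mask.data[:, :, k]
        if not sl.any():
            raise DegenerateSliceError(f"slice {k}: empty cross-section")
        radii[:, k], origins[k], cents[k] = _sample_slice(
            sl, (sx, sy), theta, max_fail_frac, k, warnings_out)
    # re-express every slice's boundary as a radius about the common
    # segment-mean axis, so axial bending appears in r_total (and can later
    # be separated into the curvature component)
    axis = cents.mean(axis=0)
    for k in range(nz):
        bx = origins[k, 0] + radii[:, k] * np.cos(theta) - axis[0]
        by = origins[k, 1] + radii[:, k] * np.sin(theta) - axis[1]
        phi = np.mod(np.arctan2(by, bx), 2 * np.pi)
        rho = np.hypot(bx, by)
        order = np.argsort(phi)
        phi_s, rho_s = phi[order], rho[order]
        phi_ext = np.concatenate([phi_s - 2 * np.pi, phi_s, phi_s + 2 * np.pi])
        rho_ext = np.tile(rho_s, 3)
        radii[:, k] = np.interp(theta, phi_ext, rho_ext)
    z_native = np.arange(nz) * sz
    z_grid = np.arange(0.0, z_native[-1] + 1e-9, dz_mm)
    r_grid = np.empty((n_theta, z_grid.size))
    for i in range(n_theta):
        r_grid[i] = np.interp(z_grid, z_native, radii[i])
    c_grid = np.column_stack([
        np.interp(z_grid, z_native, cents[:, 0]),
        np.interp(z_grid, z_native, cents[:, 1]),
    ])
    if warnings_out:
        log.info("radial_sample: %s", "; ".join(warnings_out[:10]))
    return RadialSurface(theta=theta, z=z_grid, r_total=r_grid, centroids=c_grid,
                         axis_center=(float(axis[0]), float(axis[1])),
                         warnings_=warnings_out)


def decompose(surface: RadialSurface, smoothing_span_mm: float = 15.0) -> RadialSurface:
    """Split ``r_total`` into curvature (global geometry) and shape (texture).

    The curvature surface is the centroid-drift projection plus the smoothed
    axial trend of the per-slice mean radius; the shape surface is the
    zero-theta-mean residual. The per-slice baseline ``r_mean`` absorbs what
    remains, making ``r_total = r_mean + r_curvature + r_shape`` exact.
    """
    r = surface.r_total
    m = r.mean(axis=0)  # per-slice mean radius
    m_bar = float(m.mean())
    dz = float(surface.z[1] - surface.z[0]) if surface.n_z > 1 else 1.0
    span = max(1, int(round(smoothing_span_mm / dz)))
    if span % 2 == 0:
        span += 1
    trend = ndimage.uniform_filter1d(m, size=span, mode="nearest")

    drift = surface.centroids - surface.centroids.mean(axis=0)  # (n_z, 2)
    proj = np.outer(np.cos(surface.theta), drift[:, 0]) + \
        np.outer(np.sin(surface.theta), drift[:, 1])

    r_curv = proj + (trend - m_bar)[None, :]
    r_shape = r - m[None, :] - proj
    r_mean = m - trend + m_bar
    return replace(surface, r_shape=r_shape, r_curvature=r_curv, r_mean=r_mean)


def render_unrolled(surface: RadialSurface, component: str, path,
                    rolled: bool = True):
    """Write a diagnostic rendering: unrolled grayscale map (theta horizontal,
    z vertical, brighter = topological hills) plus an optional rolled 3D view.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fld = surface.component(component)
    if rolled:
        fig = plt.figure(figsize=(10, 5))
        ax = fig.add_subplot(1, 2, 1)
        ax3 = fig.add_subplot(1, 2, 2, projection="3d")
        rr = surface.r_total
        xs = rr * np.cos(surface.theta)[:, None]
        ys = rr * np.sin(surface.theta)[:, None]
        zs = np.broadcast_to(surface.z, rr.shape)
        stride = max(1, surface.n_theta // 90)
        ax3.plot_surface(xs[::stride], ys[::stride], zs[::stride],
                         facecolors=plt.cm.gray(
                             (fld - fld.min()) / (np.ptp(fld) or 1.0))[::stride],
                         shade=False)
        ax3.set_title("rolled")
    else:
        fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(fld.T, origin="lower", cmap="gray", aspect="auto",
              extent=(0, 360, float(surface.z[0]), float(surface.z[-1])))
    ax.set_xlabel("theta (deg)")
    ax.set_ylabel("z (mm above carina)")
    ax.set_title(f"unrolled {component}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
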