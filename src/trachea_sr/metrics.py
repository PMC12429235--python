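"""Per-case trachea measurements: SR_S, SR_C, SR_T, TI and auxiliary LAA950.

This is the user-facing layer: :func:`compute_all` runs the whole pipeline
(carina detection -> cropping -> radial sampling -> decomposition -> box
counting) on one mask, and :func:`run_batch` processes a directory of masks
into a CSV, recording per-case failures without aborting.

Conventions follow the saber-sheath literature: the coronal diameter ``d_c``
is the left-right lumen extent, the sagittal diameter ``d_s`` the
anterior-posterior extent, and the tracheal index ``TI = min(d_c / d_s)``
over the window from 2 cm above the carina up to the segment top. COPD
tracheas narrow coronally, so TI < 1 and falls with disease severity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import extraction, fractal, surface as surface_mod
from .errors import DegenerateInputError, WindowError
from .mask_io import CtVolume, VoxelMask, read_mask, validate_airway_mask

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "case_id", "SR_S", "SR_C", "SR_T", "D_S", "D_C", "D_T",
    "fit_r2_S", "fit_r2_C", "fit_r2_T", "TI", "TI_slice", "n_slices",
    "laa950", "status", "config_hash",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the pipeline, hashable for provenance."""

    top_offset_mm: float = 5.0
    min_length_mm: float = 20.0
    min_branch_area_mm2: float = 20.0
    branch_persistence: int = 3
    carina_slice: int | None = None  # manual override
    n_theta: int = 360
    dz_mm: float = 1.0
    smoothing_span_mm: float = 15.0
    box_sizes: tuple[int, ...] | None = None  # None -> automatic ladder
    ti_offset_mm: float = 20.0  # window starts this far above the carina

    @property
    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.md5(payload.encode()).hexdigest()[:8]

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            import yaml

            d = yaml.safe_load(path.read_text()) or {}
        if "box_sizes" in d and d["box_sizes"] is not None:
            d["box_sizes"] = tuple(d["box_sizes"])
        return cls(**d)


@dataclass
class TracheaMetrics:
    """Complete per-case measurement record."""

    SR_S: float
    SR_C: float
    SR_T: float
    D_S: float
    D_C: float
    D_T: float
    fit_r2_S: float
    fit_r2_C: float
    fit_r2_T: float
    TI: float
    TI_slice: int
    n_slices: int
    z_carina: int
    z_top: int
    per_slice_diameters: pd.DataFrame = field(repr=False)
    laa950: float | None = None
    qc_flags: list[str] = field(default_factory=list)
    config_hash: str = ""

    def to_row(self, case_id: str = "", status: str = "ok") -> dict:
        return {
            "case_id": case_id,
            "SR_S": self.SR_S, "SR_C": self.SR_C, "SR_T": self.SR_T,
            "D_S": self.D_S, "D_C": self.D_C, "D_T": self.D_T,
            "fit_r2_S": self.fit_r2_S, "fit_r2_C": self.fit_r2_C,
            "fit_r2_T": self.fit_r2_T,
            "TI": self.TI, "TI_slice": self.TI_slice, "n_slices": self.n_slices,
            "laa950": self.laa950, "status": status, "config_hash": self.config_hash,
        }


def per_slice_diameters(surf: surface_mod.RadialSurface) -> pd.DataFrame:
    """Sub-voxel coronal and sagittal lumen extents at every axial position."""
    x = surf.axis_center[0] + surf.r_total * np.cos(surf.theta)[:, None]
    y = surf.axis_center[1] + surf.r_total * np.sin(surf.theta)[:, None]
    d_c = x.max(axis=0) - x.min(axis=0)
    d_s = y.max(axis=0) - y.min(axis=0)
    return pd.DataFrame({
        "z_mm": surf.z, "d_c_mm": d_c, "d_s_mm": d_s, "ratio": d_c / d_s,
    })


def tracheal_index(segment: extraction.TracheaSegment,
                   surf: surface_mod.RadialSurface | None = None,
                   window_mm: tuple[float, float] | None = None,
                   ti_offset_mm: float = 20.0) -> tuple[float, int, pd.DataFrame]:
    """Minimum coronal/sagittal diameter ratio on the trachea.

    The default window runs from ``ti_offset_mm`` (2 cm) above the carina to
    the segment top. Diameters come from the sub-voxel radial surface when
    provided, else from voxel extents. Returns ``(TI, TI_slice, table)`` with
    ``TI_slice`` a canonical slice index of the original mask.
    """
    sz = segment.mask.spacing[2]
    if surf is None:
        surf = surface_mod.radial_sample(segment)
    table = per_slice_diameters(surf)
    z_lo, z_hi = window_mm if window_mm is not None else (ti_offset_mm, float(surf.z[-1]))
    in_win = (table["z_mm"] >= z_lo - 1e-9) & (table["z_mm"] <= z_hi + 1e-9)
    if not in_win.any():
        raise WindowError(f"empty TI window [{z_lo}, {z_hi}] mm above the carina")
    win = table[in_win]
    idx = win["ratio"].idxmin()
    ti = float(win.loc[idx, "ratio"])
    ti_slice = segment.z_carina + int(round(win.loc[idx, "z_mm"] / sz))
    return ti, ti_slice, table


def laa950(ct: CtVolume, lung_mask: VoxelMask, threshold_hu: float = -950.0) -> float:
    """Percent of lung voxels strictly below the HU threshold (emphysema burden)."""
    if not ct.matches(lung_mask):
        raise ValueError("CT volume and lung mask differ in shape or spacing; "
                         "resample explicitly before pairing")
    lung = lung_mask.data > 0
    n = int(np.count_nonzero(lung))
    if n == 0:
        raise DegenerateInputError("lung mask has no foreground voxels")
    low = int(np.count_nonzero(ct.data[lung] < threshold_hu))
    return 100.0 * low / n


def compute_all(mask: VoxelMask, config: AnalysisConfig = AnalysisConfig(),
                ct: CtVolume | None = None,
                lung_mask: VoxelMask | None = None) -> TracheaMetrics:
    """Run the full measurement pipeline on one airway mask."""
    qc: list[str] = []
    report = validate_airway_mask(mask)
    if not report.usable:
        raise DegenerateInputError("; ".join(report.reasons) or "mask unusable")

    if config.carina_slice is not None:
        z_carina = int(config.carina_slice)
        qc.append("carina slice supplied manually")
    else:
        z_carina = extraction.find_carina(
            mask, min_branch_area_mm2=config.min_branch_area_mm2,
            persistence=config.branch_persistence)

    segment = extraction.crop_trachea(mask, z_carina,
                                      top_offset_mm=config.top_offset_mm,
                                      min_length_mm=config.min_length_mm)
    qc.extend(segment.provenance.get("flags", []))

    surf = surface_mod.radial_sample(segment, n_theta=config.n_theta,
                                     dz_mm=config.dz_mm)
    qc.extend(surf.warnings_)
    surf = surface_mod.decompose(surf, smoothing_span_mm=config.smoothing_span_mm)

    box_sizes = list(config.box_sizes) if config.box_sizes else None
    results = {}
    for comp in ("shape", "curvature", "total"):
        hm = fractal.to_heightmap(surf, comp)
        res = fractal.analyze_heightmap(hm, box_sizes, component=comp)
        qc.extend(f"{comp}: {n}" for n in res.notes)
        results[comp] = res

    ti, ti_slice, table = tracheal_index(segment, surf,
                                         ti_offset_mm=config.ti_offset_mm)
    laa = None
    if ct is not None and lung_mask is not None:
        laa = laa950(ct, lung_mask)

    return TracheaMetrics(
        SR_S=results["shape"].SR, SR_C=results["curvature"].SR,
        SR_T=results["total"].SR,
        D_S=results["shape"].D, D_C=results["curvature"].D,
        D_T=results["total"].D,
        fit_r2_S=results["shape"].fit_r2, fit_r2_C=results["curvature"].fit_r2,
        fit_r2_T=results["total"].fit_r2,
        TI=ti, TI_slice=ti_slice, n_slices=segment.n_slices,
        z_carina=segment.z_carina, z_top=segment.z_top,
        per_slice_diameters=table, laa950=laa, qc_flags=qc,
        config_hash=config.hash,
    )


def run_batch(input_dir, output_csv, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Process every mask in a directory into one CSV row per case.

    Failures are recorded per case (``status`` column) without aborting the
    batch. Rows are ordered by case id for reproducibility.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise OSError(f"not a directory: {input_dir}")
    paths = sorted(p for p in input_dir.iterdir()
                   if "".join(p.suffixes).endswith((".nii", ".nii.gz", ".mha", ".mhd")))
    rows = []
    for p in paths:
        case_id = p.name.split(".")[0]
        try:
            mask = read_mask(p)
            metrics = compute_all(mask, config)
            rows.append(metrics.to_row(case_id=case_id))
        except Exception as exc:  # noqa: BLE001 - batch must survive any single case
            log.warning("case %s failed: %s", case_id, exc)
            row = {c: np.nan for c in CSV_COLUMNS}
            row.update(case_id=case_id, status=f"failed: {type(exc).__name__}: {exc}",
                       config_hash=config.hash)
            rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    if output_csv is not None:
        df.to_csv(output_csv, index=False)
    return df
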