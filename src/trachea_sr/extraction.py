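"""Isolate the trachea-lumen analysis segment from an airway-tree mask.

The analysis segment starts ~5 mm below the most superior airway slice and
ends at the carina — the last slice, moving inferiorly, on which the lumen is
still a single cross-section. The carina is detected as a *persistent*
in-slice split of the tracked airway component: transient pinches (e.g. a
single noisy slice with two components) are ignored, and only splits into
components of at least a minimum area that persist for several consecutive
slices count as the main-bronchi bifurcation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CarinaNotFoundError, DegenerateInputError, SegmentTooShortError
from .mask_io import VoxelMask, largest_component, _STRUCT_8

log = logging.getLogger(__name__)


@dataclass
class TracheaSegment:
    """Cropped trachea-lumen mask plus the slice bookkeeping of the analysis range.

    ``mask.data[:, :, 0]`` is the carina slice; index grows superiorly.
    ``z_carina`` and ``z_top`` are canonical slice indices into the original
    mask; ``slice_range`` is inclusive.
    """

    mask: VoxelMask
    z_carina: int
    z_top: int
    provenance: dict = field(default_factory=dict)

    @property
    def slice_range(self) -> tuple[int, int]:
        return (self.z_carina, self.z_top)

    @property
    def n_slices(self) -> int:
        return self.z_top - self.z_carina + 1


def _big_component_count(sl: np.ndarray, min_px: int) -> int:
    lbl, n = ndimage.label(sl, structure=_STRUCT_8)
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    return int(np.count_nonzero(sizes >= min_px))


def find_carina(mask: VoxelMask, min_branch_area_mm2: float = 20.0,
                persistence: int = 3) -> int:
    """Slice index of the carina: the last single-lumen slice above the
    first persistent split of the airway tracked from the top.

    A split counts when the largest 26-connected component's cross-section
    divides into >= 2 in-slice 8-connected components, each of area at least
    ``min_branch_area_mm2``, on ``persistence`` consecutive slices.
    """
    if mask.foreground_count() == 0:
        raise DegenerateInputError("mask has no foreground voxels")
    sx, sy, _ = mask.spacing
    min_px = max(1, math.ceil(min_branch_area_mm2 / (sx * sy)))
    comp = largest_component(mask.data)
    nz = comp.shape[2]
    occupied = [k for k in range(nz) if comp[:, :, k].any()]
    counts = {k: _big_component_count(comp[:, :, k], min_px) for k in occupied}
    for k in sorted(occupied, reverse=True):  # superior -> inferior
        run = [k - i for i in range(persistence)]
        if all(counts.get(j, 0) >= 2 for j in run):
            carina = k + 1
            if carina not in counts:
                raise CarinaNotFoundError(
                    "airway is split on its most superior slices; no single-lumen "
                    "trachea section above the bifurcation"
                )
            log.info("carina at slice %d (persistent split below, min area %d px)",
                     carina, min_px)
            return carina
    raise CarinaNotFoundError(
        "no persistent in-slice split found; mask may contain only the trachea "
        "(supply the carina slice manually)"
    )


def crop_trachea(mask: VoxelMask, z_carina: int, top_offset_mm: float = 5.0,
                 min_length_mm: float = 20.0) -> TracheaSegment:
    """Crop the trachea lumen between ``top_offset_mm`` below the top airway
    slice and the carina, retaining one connected cross-section per slice.

    Within each analyzed slice only the 8-connected component continuous with
    the tracheal lumen (largest overlap with the retained component of the
    slice above) is kept; esophageal air or other disjoint structures are
    removed slice by slice.
    """
    sx, sy, sz = mask.spacing
    comp = largest_component(mask.data)
    nz = comp.shape[2]
    occupied = np.flatnonzero(comp.reshape(-1, nz).any(axis=0))
    if occupied.size == 0 or z_carina < 0 or z_carina >= nz:
        raise DegenerateInputError("mask has no foreground above the carina")
    topmost = int(occupied.max())
    z_top = topmost - int(round(top_offset_mm / sz))
    min_slices = int(round(min_length_mm / sz))
    if z_top - z_carina + 1 < min_slices:
        raise SegmentTooShortError(
            f"segment [{z_carina}, {z_top}] shorter than {min_length_mm} mm "
            f"({min_slices} slices)"
        )

    out = np.zeros((mask.data.shape[0], mask.data.shape[1], z_top - z_carina + 1),
                   dtype=np.uint8)
    prev: np.ndarray | None = None
    flags: list[str] = []
    for k in range(z_top, z_carina - 1, -1):
        sl = mask.data[:, :, k]
        lbl, n = ndimage.label(sl, structure=_STRUCT_8)
        if n == 0:
            raise DegenerateInputError(f"slice {k} inside the analysis range is empty")
        if prev is None:
            # seed from the largest component of the 3D airway on the top slice
            seed = comp[:, :, k]
            if not seed.any():
                seed = sl
            overlaps = ndimage.sum_labels(seed.astype(float), lbl,
                                          index=np.arange(1, n + 1))
        else:
            overlaps = ndimage.sum_labels(prev.astype(float), lbl,
                                          index=np.arange(1, n + 1))
        if overlaps.max() == 0:
            # lumen lost continuity; fall back to the largest in-slice component
            sizes = ndimage.sum_labels(np.ones_like(lbl), lbl,
                                       index=np.arange(1, n + 1))
            pick = 1 + int(np.argmax(sizes))
            flags.append(f"slice {k}: no overlap with slice above, kept largest component")
        else:
            pick = 1 + int(np.argmax(overlaps))
        keep = (lbl == pick).astype(np.uint8)
        out[:, :, k - z_carina] = keep
        prev = keep

    seg_mask = VoxelMask(data=out, spacing=mask.spacing, origin=mask.origin)
    prov = {
        "topmost_slice": topmost,
        "top_offset_mm": top_offset_mm,
        "z_top": z_top,
        "z_carina": z_carina,
        "flags": flags,
    }
    if flags:
        log.warning("crop_trachea: %s", "; ".join(flags))
    return TracheaSegment(mask=seg_mask, z_carina=z_carina, z_top=z_top, provenance=prov)
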