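"""Reading, writing and validating segmentation masks and CT volumes.

Arrays follow one canonical convention throughout the package:

* axis 0 (x): patient left-right, the *coronal-diameter* axis
* axis 1 (y): anterior-posterior, the *sagittal-diameter* axis
* axis 2 (z): inferior -> superior (index grows toward the head)

NIfTI files are reoriented to RAS+ on load, which realizes exactly this
convention; the orientation the file arrived in is recorded so the transform
is auditable. Any nonzero label is treated as foreground: airway masks
exported by different tools use different label schemes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy import ndimage

from .errors import DimensionalityError, MaskIOError, MetadataError

log = logging.getLogger(__name__)

_CANONICAL_AXCODES = ("R", "A", "S")


@dataclass
class VoxelMask:
    """3D binary mask with anisotropic voxel spacing (mm), canonical axes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    source_orientation: tuple[str, str, str] = _CANONICAL_AXCODES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got ndim={self.data.ndim}")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask data must contain only {0, 1}")
        self.data = self.data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive finite values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def foreground_count(self) -> int:
        return int(self.data.sum())


@dataclass
class CtVolume:
    """3D CT attenuation volume in Hounsfield units, canonical axes."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise DimensionalityError(f"CT volume must be 3D, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive finite values, got {self.spacing}")

    def matches(self, mask: VoxelMask) -> bool:
        """Shape and spacing match exactly; no implicit resampling is done."""
        return self.data.shape == mask.data.shape and np.allclose(self.spacing, mask.spacing)


def _load_canonical(path: Path):
    """Load a NIfTI/MetaImage file reoriented to RAS+; return (array, spacing, origin, src_axcodes)."""
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:  # sitk raises RuntimeError
            raise MaskIOError(f"cannot read {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise DimensionalityError(f"{path}: expected 3D image, got {img.GetDimension()}D")
        src = "".join(
            sitk.DICOMOrientImageFilter_GetOrientationFromDirectionCosines(img.GetDirection())
        )
        img = sitk.DICOMOrient(img, "RAS")
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # sitk arrays are (z,y,x)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
        return arr, spacing, origin, tuple(src)

    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise MaskIOError(f"cannot read {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got {img.ndim}D")
    src_axcodes = nib.orientations.aff2axcodes(img.affine)
    img = nib.as_closest_canonical(img)
    arr = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if not all(np.isfinite(s) and s > 0 for s in spacing):
        raise MetadataError(f"{path}: missing or zero voxel spacing {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return arr, spacing, origin, src_axcodes


def read_mask(path) -> VoxelMask:
    """Read a label image and return a binarized :class:`VoxelMask` in canonical orientation."""
    path = Path(path)
    arr, spacing, origin, src = _load_canonical(path)
    data = (np.asarray(arr) != 0).astype(np.uint8)
    if data.sum() == 0:
        log.warning("mask %s contains no foreground voxels", path)
    if src != _CANONICAL_AXCODES:
        log.info("mask %s reoriented from %s to RAS", path, src)
    return VoxelMask(data=data, spacing=spacing, origin=origin, source_orientation=tuple(src))


def read_ct(path) -> CtVolume:
    """Read a CT attenuation volume (HU) in canonical orientation."""
    path = Path(path)
    arr, spacing, origin, _src = _load_canonical(path)
    return CtVolume(data=np.asarray(arr, dtype=np.float32), spacing=spacing, origin=origin)


def write_mask(mask: VoxelMask, path) -> Path:
    """Write a mask to NIfTI (or MetaImage) with spacing in the header; round-trips with read_mask."""
    path = Path(path)
    if mask.foreground_count() == 0:
        warnings.warn(f"writing mask with no foreground voxels to {path}", stacklevel=2)
        log.warning("writing empty mask to %s", path)
    suffixes = "".join(path.suffixes)
    try:
        if suffixes.endswith((".mha", ".mhd")):
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(mask.data.transpose(2, 1, 0))
            img.SetSpacing(tuple(float(s) for s in mask.spacing))
            img.SetOrigin(tuple(float(o) for o in mask.origin))
            sitk.WriteImage(img, str(path))
        else:
            affine = np.diag(list(mask.spacing) + [1.0])
            affine[:3, 3] = mask.origin
            nib.save(nib.Nifti1Image(mask.data, affine), str(path))
    except OSError as exc:
        raise MaskIOError(f"cannot write {path}: {exc}") from exc
    return path


@dataclass
class ValidationReport:
    """Summary of a mask's suitability for trachea extraction."""

    n_foreground: int
    n_components: int
    largest_in_top_slices: bool
    per_slice_counts: np.ndarray = field(repr=False)
    usable: bool = True
    reasons: list[str] = field(default_factory=list)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def largest_component(data: np.ndarray) -> np.ndarray:
    """Binary image of the largest 26-connected component (zeros if empty)."""
    lbl, n = ndimage.label(data, structure=_STRUCT_26)
    if n == 0:
        return np.zeros_like(data)
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    return (lbl == (1 + int(np.argmax(sizes)))).astype(np.uint8)


def validate_airway_mask(mask: VoxelMask, top_band: int = 10) -> ValidationReport:
    """Report foreground size, connectivity and per-slice cross-section counts.

    A mask is flagged unusable when it has no foreground or when the largest
    26-connected component is absent from the ``top_band`` most superior
    slices of the volume (no trachea entering from above).
    """
    n_fg = mask.foreground_count()
    lbl, n_comp = ndimage.label(mask.data, structure=_STRUCT_26)
    nz = mask.data.shape[2]
    reasons: list[str] = []
    if n_fg == 0:
        return ValidationReport(0, 0, False, np.zeros(nz, dtype=int), False, ["no foreground voxels"])

    comp = largest_component(mask.data)
    counts = np.zeros(nz, dtype=int)
    for k in range(nz):
        _, c = ndimage.label(comp[:, :, k], structure=_STRUCT_8)
        counts[k] = c
    in_top = bool(comp[:, :, max(0, nz - top_band):].any())
    if not in_top:
        reasons.append("no component at superior slices")
    return ValidationReport(
        n_foreground=n_fg,
        n_components=int(n_comp),
        largest_in_top_slices=in_top,
        per_slice_counts=counts,
        usable=not reasons,
        reasons=reasons,
    )
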