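"""Volumetric image and segmentation containers.

A :class:`VolumeImage` is a 3D scalar grid with physical spacing, the unit
all preprocessing and filtering act on.  Arrays are indexed ``(z, y, x)``
(slice, row, column — the convention SimpleITK/nibabel produce when a
volume is loaded into numpy), while ``spacing`` and ``origin`` are given in
physical ``(x, y, z)`` order in millimetres, matching the image headers.

A :class:`SegmentationMask` is an integer label grid on the same geometry,
plus a dictionary naming each region of interest.  Nested anatomical
regions (tumor inside peripheral zone inside whole gland) are stored with
one code per voxel and a *set* of codes per ROI name, so e.g. the
``whole_gland`` ROI includes the tumor and peripheral-zone codes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np


class GeometryError(ValueError):
    """Raised when a grid, spacing or lesion geometry is invalid."""


class MissingROIError(KeyError):
    """Raised when a named region of interest is absent or empty."""


class DegenerateInputError(ValueError):
    """Raised when an input is constant where variation is required."""


@dataclasses.dataclass(frozen=True)
class VolumeImage:
    """3D scalar image with physical geometry.

    Parameters
    ----------
    voxels
        Array of shape ``(nz, ny, nx)`` with finite intensities.
    spacing
        Voxel size ``(sx, sy, sz)`` in mm; all components positive.
    origin
        Physical coordinate of the first voxel, ``(x0, y0, z0)`` in mm.
    axis_order
        Tag recording the array-axis convention; always ``"zyx"`` here.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 3 or vox.size == 0:
            raise GeometryError(f"expected a non-empty 3D grid, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise GeometryError("image intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise GeometryError(f"spacing must be three positive components, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if self.axis_order != "zyx":
            raise GeometryError(f"unsupported axis convention {self.axis_order!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing_zyx(self) -> tuple[float, float, float]:
        """Spacing reordered to match array axes (sz, sy, sx)."""
        sx, sy, sz = self.spacing
        return (sz, sy, sx)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_voxels(self, voxels: np.ndarray) -> "VolumeImage":
        """New image with the same geometry and different intensities."""
        return VolumeImage(voxels=voxels, spacing=self.spacing, origin=self.origin)

    def same_geometry(self, other: "VolumeImage | SegmentationMask") -> bool:
        shape = other.labels.shape if isinstance(other, SegmentationMask) else other.shape
        spacing = other.spacing
        return self.shape == shape and np.allclose(self.spacing, spacing)


@dataclasses.dataclass(frozen=True)
class SegmentationMask:
    """Integer label grid naming regions of interest.

    ``roi_codes`` maps an ROI name to the label codes it comprises;
    several codes per name support nested anatomy.
    """

    labels: np.ndarray
    roi_codes: Mapping[str, tuple[int, ...]]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, lab.astype(np.int32)):
                raise GeometryError("labels must be integers")
            lab = lab.astype(np.int32)
        if lab.ndim != 3 or lab.size == 0:
            raise GeometryError(f"expected a non-empty 3D label grid, got shape {lab.shape}")
        if lab.min() < 0:
            raise GeometryError("labels must be non-negative")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        codes = {
            str(name): tuple(int(c) for c in (v if isinstance(v, (tuple, list, set, frozenset)) else (v,)))
            for name, v in dict(self.roi_codes).items()
        }
        object.__setattr__(self, "roi_codes", codes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def roi_mask(self, roi: str) -> np.ndarray:
        """Boolean voxel mask for a named ROI.

        Raises :class:`MissingROIError` if the name is unknown or the
        region contains no voxels.
        """
        if roi not in self.roi_codes:
            raise MissingROIError(f"unknown ROI {roi!r}; known: {sorted(self.roi_codes)}")
        mask = np.isin(self.labels, self.roi_codes[roi])
        if not mask.any():
            raise MissingROIError(f"ROI {roi!r} is empty")
        return mask

    def roi_values(self, img: VolumeImage, roi: str) -> np.ndarray:
        """Intensities of ``img`` inside a named ROI (1D array)."""
        if not img.same_geometry(self):
            raise GeometryError("image and mask geometry differ")
        return img.voxels[self.roi_mask(roi)]

    def with_labels(self, labels: np.ndarray) -> "SegmentationMask":
        return SegmentationMask(labels=labels, roi_codes=self.roi_codes,
                                spacing=self.spacing, origin=self.origin)


# ---------------------------------------------------------------------------
# File I/O — NRRD through SimpleITK (default), NIfTI-1 through nibabel.
# ---------------------------------------------------------------------------

def write_image(path: str | Path, img: VolumeImage) -> None:
    """Write a volume as .nrrd (SimpleITK) or .nii/.nii.gz (nibabel)."""
    path = Path(path)
    if path.suffix == ".nrrd":
        import SimpleITK as sitk

        itk = sitk.GetImageFromArray(img.voxels)
        itk.SetSpacing(img.spacing)
        itk.SetOrigin(img.origin)
        sitk.WriteImage(itk, str(path))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        sx, sy, sz = img.spacing
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = img.origin
        # nibabel expects (x, y, z) data order
        nib.save(nib.Nifti1Image(img.voxels.transpose(2, 1, 0), affine), str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def read_image(path: str | Path) -> VolumeImage:
    path = Path(path)
    if path.suffix == ".nrrd":
        import SimpleITK as sitk

        itk = sitk.ReadImage(str(path))
        return VolumeImage(voxels=sitk.GetArrayFromImage(itk),
                           spacing=tuple(itk.GetSpacing()),
                           origin=tuple(itk.GetOrigin()))
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nii = nib.load(str(path))
        data = np.asarray(nii.dataobj, dtype=np.float64).transpose(2, 1, 0)
        zooms = nii.header.get_zooms()[:3]
        origin = tuple(float(v) for v in nii.affine[:3, 3])
        return VolumeImage(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)
    raise ValueError(f"unsupported image format: {path.name}")


def write_mask(path: str | Path, mask: SegmentationMask) -> None:
    """Write a label grid; ROI code dictionary goes to a sidecar JSON."""
    import json

    path = Path(path)
    img = VolumeImage(voxels=mask.labels.astype(np.float64),
                      spacing=mask.spacing, origin=mask.origin)
    write_image(path, img)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({k: list(v) for k, v in mask.roi_codes.items()},
                                  indent=0, sort_keys=True))


def read_mask(path: str | Path) -> SegmentationMask:
    import json

    path = Path(path)
    img = read_image(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    codes = {k: tuple(v) for k, v in json.loads(sidecar.read_text()).items()}
    return SegmentationMask(labels=np.rint(img.voxels).astype(np.int32),
                            roi_codes=codes, spacing=img.spacing, origin=img.origin)
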