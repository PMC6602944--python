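"""Synthetic test-retest phantom cohorts with known variance structure.

Real test-retest MR cohorts mix several variance sources that a
repeatability analysis must separate: stable anatomy (between-subject
variance), scan-to-scan noise and global intensity drift (within-subject
variance), and segmentation inconsistency between timepoints.  The
phantom generator emulates exactly these ingredients on a small
prostate-like geometry so that the theoretical repeatability of simple
features is known in closed form:

* an ellipsoidal gland with a posterior peripheral-zone band, a
  spherical lesion inside it, and a homogeneous low-intensity
  muscle-like reference cylinder;
* a per-subject intensity shift (SD ``sigma_b``) and a per-subject
  smoothed Gaussian random texture field, both shared across the two
  timepoints — the *between-subject* anatomy;
* per-scan white noise (SD ``sigma_w``), a per-scan global gain/offset
  drift, and optional single-voxel dilation/erosion jitter of the tumor
  contour — the *within-subject* variation.

One master seed drives per-(subject, timepoint) derived substreams, so
cohorts are bit-reproducible and stable under changes of ``n_subjects``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (GeometryError, SegmentationMask, VolumeImage,
                      read_image, read_mask, write_image, write_mask)

TIMEPOINTS = ("test", "retest")

#: label codes of the phantom anatomy
LABELS = {"background": 0, "gland": 1, "peripheral_zone": 2, "tumor": 3,
          "muscle": 4}

#: ROI name -> label codes (nested anatomy: PZ contains the tumor, the
#: whole gland contains both)
ROI_CODES = {
    "tumor": (3,),
    "peripheral_zone": (2, 3),
    "whole_gland": (1, 2, 3),
    "muscle_reference": (4,),
}


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of one phantom cohort.

    Intensities are in arbitrary MR-like units.  ``sigma_b`` is the SD
    of the per-subject global intensity shift (between-subject);
    ``sigma_w`` the per-voxel scan-noise SD (within-subject).  Gain and
    offset drift are drawn per scan as ``1 + N(0, gain_sd)`` and
    ``N(0, offset_sd)``; set both SDs to zero for fixed acquisition.
    ``boundary_jitter`` is the probability that the tumor contour of a
    given scan is dilated or eroded by one voxel.
    """

    n_subjects: int = 15
    shape: tuple[int, int, int] = (16, 48, 48)         # (nz, ny, nx)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)  # (sx, sy, sz) mm
    tissue_means: Mapping[str, float] = dataclasses.field(default_factory=lambda: {
        "background": 50.0, "gland": 220.0, "peripheral_zone": 260.0,
        "tumor": 180.0, "muscle": 80.0})
    sigma_b: float = 20.0
    sigma_w: float = 15.0
    texture_sd: float = 10.0
    muscle_texture_sd: float = 2.0
    texture_corr_mm: float = 2.0
    gain_sd: float = 0.05
    offset_sd: float = 10.0
    boundary_jitter: float = 0.3
    lesion_radius_mm: float = 6.0
    lesion_radius_sd_mm: float = 1.0
    lesion_center_jitter_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("sigma_b", "sigma_w", "texture_sd", "muscle_texture_sd",
                     "gain_sd", "offset_sd", "lesion_radius_sd_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.boundary_jitter <= 1.0:
            raise ValueError("boundary_jitter is a probability")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion_radius_mm must be positive")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclasses.dataclass(frozen=True)
class CohortRecord:
    subject_id: str
    timepoint: str
    image: VolumeImage
    mask: SegmentationMask


# ---------------------------------------------------------------------------
# Geometry rasterization
# ---------------------------------------------------------------------------

def _physical_coords(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sx, sy, sz = spacing
    nz, ny, nx = shape
    z = np.arange(nz)[:, None, None] * sz
    y = np.arange(ny)[None, :, None] * sy
    x = np.arange(nx)[None, None, :] * sx
    return z, y, x


def _anatomy_labels(spec: PhantomSpec, lesion_center_mm: tuple[float, float, float],
                    lesion_radius_mm: float) -> np.ndarray:
    """True anatomy label grid; raises GeometryError if the lesion sticks out."""
    sx, sy, sz = spec.spacing
    nz, ny, nx = spec.shape
    ext = (nz * sz, ny * sy, nx * sx)  # physical extents (z, y, x)
    cz_l, cy_l, cx_l = lesion_center_mm
    for c, e in zip(lesion_center_mm, ext):
        if c - lesion_radius_mm < 0 or c + lesion_radius_mm > e:
            raise GeometryError("lesion does not fit inside the grid")

    z, y, x = _physical_coords(spec.shape, spec.spacing)
    cz, cy, cx = ext[0] / 2, ext[1] / 2, ext[2] / 2
    az, ay, ax = 0.35 * ext[0], 0.25 * ext[1], 0.3 * ext[2]  # gland semi-axes
    gland = (((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2) <= 1.0

    labels = np.zeros(spec.shape, dtype=np.int32)
    labels[gland] = LABELS["gland"]
    labels[gland & (y > cy)] = LABELS["peripheral_zone"]

    tumor = ((z - cz_l) ** 2 + (y - cy_l) ** 2 + (x - cx_l) ** 2) <= lesion_radius_mm ** 2
    if not tumor.any():
        raise GeometryError("lesion radius below voxel resolution")
    labels[tumor] = LABELS["tumor"]

    # homogeneous muscle-like reference: anterior cylinder along z
    my, mx, mr = 0.15 * ext[1], cx, 4.0
    muscle = (((y - my) ** 2 + (x - mx) ** 2) <= mr ** 2) & \
        (np.abs(z - cz) <= 0.3 * ext[0]) & (labels == 0)
    labels[muscle] = LABELS["muscle"]
    return labels


def _nominal_lesion_center(spec: PhantomSpec) -> tuple[float, float, float]:
    sx, sy, sz = spec.spacing
    nz, ny, nx = spec.shape
    ext = (nz * sz, ny * sy, nx * sx)
    # centred in z/x, halfway into the posterior (peripheral-zone) band
    return (ext[0] / 2, ext[1] / 2 + spec.lesion_radius_mm, ext[2] / 2)


def _mean_map(spec: PhantomSpec, labels: np.ndarray) -> np.ndarray:
    out = np.empty(labels.shape, dtype=np.float64)
    for tissue, code in LABELS.items():
        out[labels == code] = spec.tissue_means[tissue]
    return out


def _texture_field(spec: PhantomSpec, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise, rescaled to unit voxel SD, scaled per tissue."""
    if spec.texture_sd == 0.0 and spec.muscle_texture_sd == 0.0:
        return np.zeros(labels.shape)
    field = rng.standard_normal(labels.shape)
    sigma_vox = [spec.texture_corr_mm / s for s in
                 (spec.spacing[2], spec.spacing[1], spec.spacing[0])]  # (z, y, x)
    field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="reflect")
    sd = field.std()
    if sd > 0:
        field /= sd
    scale = np.where(labels == LABELS["muscle"], spec.muscle_texture_sd, spec.texture_sd)
    return field * scale


def _jitter_tumor(labels: np.ndarray, spec: PhantomSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Segmentation labels for one scan: tumor contour dilated/eroded by
    one voxel with probability ``boundary_jitter``; never emptied."""
    out = labels.copy()
    if rng.random() >= spec.boundary_jitter:
        return out
    tumor = labels == LABELS["tumor"]
    struct = ndimage.generate_binary_structure(3, 1)
    if rng.random() < 0.5:
        jittered = ndimage.binary_dilation(tumor, structure=struct)
    else:
        jittered = ndimage.binary_erosion(tumor, structure=struct)
        if not jittered.any():
            return out
    out[tumor & ~jittered] = LABELS["peripheral_zone"]
    out[jittered] = LABELS["tumor"]
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _subject_rng(spec: PhantomSpec, subject: int, scan: int | None = None) -> np.random.Generator:
    key = (subject,) if scan is None else (subject, scan)
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=key))


def generate_subject(spec: PhantomSpec, subject: int) -> list[CohortRecord]:
    """Both timepoints for one subject index."""
    srng = _subject_rng(spec, subject)
    shift = srng.normal(0.0, spec.sigma_b)
    radius = max(spec.spacing[2], spec.lesion_radius_mm +
                 srng.normal(0.0, spec.lesion_radius_sd_mm))
    center = tuple(c + j for c, j in zip(
        _nominal_lesion_center(spec),
        srng.uniform(-spec.lesion_center_jitter_mm, spec.lesion_center_jitter_mm, 3)))
    labels = _anatomy_labels(spec, center, radius)
    anatomy = _mean_map(spec, labels) + shift + _texture_field(spec, labels, srng)

    records = []
    for t, timepoint in enumerate(TIMEPOINTS):
        rng = _subject_rng(spec, subject, t)
        gain = 1.0 + (rng.normal(0.0, spec.gain_sd) if spec.gain_sd > 0 else 0.0)
        offset = rng.normal(0.0, spec.offset_sd) if spec.offset_sd > 0 else 0.0
        noise = rng.normal(0.0, spec.sigma_w, spec.shape) if spec.sigma_w > 0 else 0.0
        voxels = (anatomy + noise) * gain + offset
        mask = SegmentationMask(labels=_jitter_tumor(labels, spec, rng),
                                roi_codes=ROI_CODES, spacing=spec.spacing)
        records.append(CohortRecord(
            subject_id=f"sub{subject:03d}", timepoint=timepoint,
            image=VolumeImage(voxels=voxels, spacing=spec.spacing), mask=mask))
    return records


def generate_cohort(spec: PhantomSpec) -> list[CohortRecord]:
    """All (subject, timepoint) records: exactly 2 per subject, in order."""
    out: list[CohortRecord] = []
    for s in range(spec.n_subjects):
        out.extend(generate_subject(spec, s))
    return out


# ---------------------------------------------------------------------------
# Ground-truth repeatability of the ROI-mean feature
# ---------------------------------------------------------------------------

def expected_roi_voxel_count(spec: PhantomSpec, roi: str = "tumor") -> int:
    """Voxel count of the ROI in the nominal (unjittered, mean-radius) anatomy."""
    labels = _anatomy_labels(spec, _nominal_lesion_center(spec), spec.lesion_radius_mm)
    return int(np.isin(labels, ROI_CODES[roi]).sum())


def theoretical_icc_roi_mean(spec: PhantomSpec, roi: str = "tumor") -> float:
    """Closed-form ICC(1,1) of the ROI-mean intensity feature.

    Under fixed gain/offset the ROI mean of one scan is
    ``mu + b_s + mean(noise)`` with Var(b_s) = sigma_b^2 and
    Var(mean(noise)) = sigma_w^2 / N for N the expected ROI voxel count,
    so ICC = sigma_b^2 / (sigma_b^2 + sigma_w^2 / N).

    The formula ignores contour jitter and assumes the per-subject
    texture field contributes negligibly to the ROI mean (exact when
    ``texture_sd`` = 0); it requires gain and offset drift disabled,
    since a random affine per scan has no closed form.  Returns NaN when
    both variance components vanish.
    """
    if spec.gain_sd != 0.0 or spec.offset_sd != 0.0:
        raise ValueError("closed form requires gain_sd = offset_sd = 0")
    var_b = spec.sigma_b ** 2
    var_w = spec.sigma_w ** 2 / expected_roi_voxel_count(spec, roi)
    if var_b == 0.0 and var_w == 0.0:
        return float("nan")
    return var_b / (var_b + var_w)


def calibrate_sigma_b(spec: PhantomSpec, target_icc: float, roi: str = "tumor") -> PhantomSpec:
    """Spec whose theoretical ROI-mean ICC equals ``target_icc``.

    Solves sigma_b^2 = target/(1-target) * sigma_w^2/N with all other
    parameters unchanged.
    """
    if not 0.0 <= target_icc < 1.0:
        raise ValueError("target_icc must be in [0, 1)")
    var_w = spec.sigma_w ** 2 / expected_roi_voxel_count(spec, roi)
    return spec.replace(sigma_b=float(np.sqrt(target_icc / (1.0 - target_icc) * var_w)))


# ---------------------------------------------------------------------------
# Worked fixtures for oracle tests
# ---------------------------------------------------------------------------

def _fixture_cube10():
    vox = np.full((10, 10, 10), 100.0)
    labels = np.ones((10, 10, 10), dtype=np.int32)
    return vox, labels


def _fixture_checker2x2():
    vox = np.array([[[1.0, 2.0], [1.0, 2.0]]])
    labels = np.ones((1, 2, 2), dtype=np.int32)
    return vox, labels


def _fixture_constant():
    vox = np.full((5, 5, 5), 7.0)
    labels = np.ones((5, 5, 5), dtype=np.int32)
    return vox, labels


def _fixture_impulse21():
    vox = np.zeros((21, 21, 21))
    vox[10, 10, 10] = 1.0
    labels = np.ones((21, 21, 21), dtype=np.int32)
    return vox, labels


_FIXTURES = {"cube10": _fixture_cube10, "checker2x2": _fixture_checker2x2,
             "constant": _fixture_constant, "impulse21": _fixture_impulse21}


def worked_fixture(name: str) -> tuple[VolumeImage, SegmentationMask]:
    """Tiny deterministic (image, mask) pairs used by hand-worked tests.

    The mask's single ROI is named ``"roi"`` and covers every voxel.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    vox, labels = _FIXTURES[name]()
    return (VolumeImage(voxels=vox),
            SegmentationMask(labels=labels, roi_codes={"roi": (1,)}))


# ---------------------------------------------------------------------------
# Cohort persistence (NRRD default, NIfTI optional) + manifest CSV
# ---------------------------------------------------------------------------

def write_cohort(records: list[CohortRecord], outdir: str | Path,
                 fmt: str = "nrrd") -> Path:
    """Write images/masks plus a manifest CSV; returns the manifest path."""
    ext = {"nrrd": ".nrrd", "nifti": ".nii.gz"}[fmt]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        stem = f"{rec.subject_id}_{rec.timepoint}"
        image_path = outdir / f"{stem}_image{ext}"
        mask_path = outdir / f"{stem}_mask{ext}"
        write_image(image_path, rec.image)
        write_mask(mask_path, rec.mask)
        rows.append({"subject_id": rec.subject_id, "timepoint": rec.timepoint,
                     "image_path": image_path.name, "mask_path": mask_path.name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest: str | Path) -> Iterator[CohortRecord]:
    manifest = Path(manifest)
    base = manifest.parent
    for row in pd.read_csv(manifest, dtype={"subject_id": str, "timepoint": str}).itertuples():
        yield CohortRecord(subject_id=row.subject_id, timepoint=row.timepoint,
                           image=read_image(base / row.image_path),
                           mask=read_mask(base / row.mask_path))
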