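"""Intensity normalization of whole images prior to filtering and extraction.

MR signal intensity is relative: the same tissue can map to different raw
values between scans, which destroys comparability of intensity-based
features.  Two affine normalization schemes are provided:

* **whole-image**: scale and shift so the image mean becomes 300 and the
  standard deviation 100 (most values then fall in 0–600 for roughly
  Gaussian intensity histograms);
* **reference-region**: fit the affine map on a designated homogeneous
  reference ROI (e.g. muscle) so its mean becomes 100 and SD 10, then
  apply that single map to every voxel of the image.

Both are pure scale-and-shift: voxel rank order, skewness and kurtosis of
any sub-region are unchanged.  Standard deviations use the population
(divide-by-N) convention throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumes import DegenerateInputError, SegmentationMask, VolumeImage

#: normalization mode names as they appear in run configs
NORMALIZATION_MODES = ("none", "whole_image", "reference_region")

#: conventional targets: whole image -> (300, 100); reference region -> (100, 10)
DEFAULT_TARGETS = {"whole_image": (300.0, 100.0), "reference_region": (100.0, 10.0)}


@dataclasses.dataclass(frozen=True)
class NormalizationSpec:
    """One normalization choice of the processing grid.

    ``target_mean``/``target_sd`` default per mode; ``reference_label``
    names the ROI the affine map is fitted on (reference_region mode).
    """

    mode: str = "none"
    target_mean: float | None = None
    target_sd: float | None = None
    reference_label: str = "muscle_reference"

    def __post_init__(self) -> None:
        if self.mode not in NORMALIZATION_MODES:
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        mean, sd = DEFAULT_TARGETS.get(self.mode, (0.0, 1.0))
        if self.target_mean is None:
            object.__setattr__(self, "target_mean", mean)
        if self.target_sd is None:
            object.__setattr__(self, "target_sd", sd)
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")

    @property
    def fingerprint(self) -> str:
        return self.mode


def _affine_from_stats(mean: float, sd: float, target_mean: float, target_sd: float) -> tuple[float, float]:
    """Coefficients (a, b) of the map x -> a*x + b taking (mean, sd) to targets."""
    a = target_sd / sd
    return a, target_mean - a * mean


def normalize_whole_image(img: VolumeImage, spec: NormalizationSpec | None = None) -> VolumeImage:
    """Scale and shift all voxels so the whole-image mean/SD hit the targets.

    Raises :class:`DegenerateInputError` for a constant image (SD = 0).
    """
    spec = spec or NormalizationSpec(mode="whole_image")
    mean = float(img.voxels.mean())
    sd = float(img.voxels.std())  # population SD
    if sd == 0.0:
        raise DegenerateInputError("cannot normalize a constant image")
    a, b = _affine_from_stats(mean, sd, spec.target_mean, spec.target_sd)
    return img.with_voxels(a * img.voxels + b)


def normalize_reference_region(img: VolumeImage, mask: SegmentationMask,
                               spec: NormalizationSpec | None = None) -> VolumeImage:
    """Fit the affine map on the reference ROI, apply it to the whole image.

    After the map, the reference-ROI mean equals ``target_mean`` and its
    SD equals ``target_sd``; all other voxels move under the same map.
    """
    spec = spec or NormalizationSpec(mode="reference_region")
    ref = mask.roi_values(img, spec.reference_label)
    sd = float(ref.std())
    if sd == 0.0:
        raise DegenerateInputError("reference ROI is constant; cannot fit scale")
    a, b = _affine_from_stats(float(ref.mean()), sd, spec.target_mean, spec.target_sd)
    return img.with_voxels(a * img.voxels + b)


def apply_normalization(img: VolumeImage, mask: SegmentationMask | None,
                        spec: NormalizationSpec) -> VolumeImage:
    """Dispatch on ``spec.mode``; ``none`` returns the input unchanged."""
    if spec.mode == "none":
        return img
    if spec.mode == "whole_image":
        return normalize_whole_image(img, spec)
    if mask is None:
        raise ValueError("reference_region normalization requires a mask")
    return normalize_reference_region(img, mask, spec)
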