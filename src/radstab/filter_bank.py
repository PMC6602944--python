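"""Derived-image filter bank applied before feature extraction.

The bank produces derived images from a (possibly normalized) original:

* ``original`` — the unchanged image;
* ``log`` — Laplacian-of-Gaussian at a physical scale ``sigma_mm``
  (band-pass; emphasizes blob-like structure of roughly that size);
* ``wavelet`` — one sub-band of a single-level undecimated (stationary)
  wavelet transform, one high-/low-pass choice per axis (8 sub-bands in
  3D: LLL … HHH);
* four single-voxel intensity transforms — ``square`` (x^2),
  ``squareroot`` (sqrt|x|), ``logarithm`` (log(|x|+1)) and
  ``exponential`` (e^x) — whose outputs are linearly rescaled back to the
  original image magnitude range with the original sign restored.

All filters preserve grid shape, spacing and origin, so downstream shape
features are identical across the whole bank.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volumes import VolumeImage

FILTER_KINDS = ("original", "log", "wavelet", "square", "squareroot",
                "logarithm", "exponential")

DEFAULT_LOG_SIGMAS_MM = (1.0, 2.0, 3.0, 4.0, 5.0)
DEFAULT_WAVELET = "coif1"

#: input magnitude above which the exponential transform pre-scales its
#: argument to avoid float overflow (exp(700) overflows double)
_EXP_GUARD = 20.0


@dataclasses.dataclass(frozen=True)
class FilterSpec:
    """One pre-filter of the processing grid.

    ``subband`` letters are given per axis in physical (x, y, z) order,
    e.g. ``"HLH"`` = high-pass along x, low-pass along y, high-pass
    along z; for single-slice (2D) processing the string has two letters
    (x, y).
    """

    kind: str = "original"
    sigma_mm: float | None = None
    subband: str | None = None
    wavelet: str = DEFAULT_WAVELET

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.kind == "log":
            if self.sigma_mm is None or self.sigma_mm <= 0:
                raise ValueError("log filter requires sigma_mm > 0")
        if self.kind == "wavelet":
            if not self.subband or set(self.subband) - {"L", "H"}:
                raise ValueError(f"invalid wavelet subband {self.subband!r}")

    @property
    def fingerprint(self) -> str:
        """Config-string form, used in feature keys (e.g. 'log:sigma=3.0')."""
        if self.kind == "log":
            return f"log:sigma={self.sigma_mm:g}"
        if self.kind == "wavelet":
            return f"wavelet:{self.subband}"
        return self.kind


def parse_filter_spec(text: str) -> FilterSpec:
    """Inverse of :attr:`FilterSpec.fingerprint`."""
    if text.startswith("log:sigma="):
        return FilterSpec(kind="log", sigma_mm=float(text.split("=", 1)[1]))
    if text.startswith("wavelet:"):
        return FilterSpec(kind="wavelet", subband=text.split(":", 1)[1])
    return FilterSpec(kind=text)


# ---------------------------------------------------------------------------
# Laplacian of Gaussian in physical space
# ---------------------------------------------------------------------------

def log_kernels_1d(sigma_vox: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1D Gaussian smoothing and second-derivative kernels.

    Both are samples of the analytic Gaussian (and its second derivative)
    at integer offsets, truncated at 4 sigma, sharing the normalization
    constant that makes the smoothing kernel sum to one.  The derivative
    kernel is mean-corrected so its taps sum to exactly zero (zero
    response on constant images).
    """
    radius = max(1, int(np.ceil(4.0 * sigma_vox)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x ** 2) / (2.0 * sigma_vox ** 2))
    c = 1.0 / g.sum()
    k0 = c * g
    k2 = c * (x ** 2 - sigma_vox ** 2) / sigma_vox ** 4 * np.exp(-(x ** 2) / (2.0 * sigma_vox ** 2))
    k2 -= k2.sum() / k2.size
    return k0, k2


def _laplacian_of_gaussian(img: VolumeImage, sigma_mm: float) -> np.ndarray:
    """Sum over axes of the second Gaussian derivative, in 1/mm^2 units.

    Per-axis Gaussian SD is ``sigma_mm / spacing_axis`` voxels, so the
    physical scale is isotropic even on anisotropic grids.  Axes with a
    single voxel (e.g. single-slice images) are skipped.  Boundary:
    symmetric reflection.
    """
    spacing_zyx = img.spacing_zyx
    out = np.zeros(img.shape, dtype=np.float64)
    kernels = [log_kernels_1d(sigma_mm / s) for s in spacing_zyx]
    active = [ax for ax in range(3) if img.shape[ax] > 1]
    for deriv_ax in active:
        term = img.voxels
        for ax in active:
            k0, k2 = kernels[ax]
            kern = k2 if ax == deriv_ax else k0
            term = ndimage.correlate1d(term, kern, axis=ax, mode="reflect")
        out += term / spacing_zyx[deriv_ax] ** 2
    return out


# ---------------------------------------------------------------------------
# Stationary wavelet sub-bands
# ---------------------------------------------------------------------------

def _wavelet_subband(img: VolumeImage, subband: str, wavelet: str) -> np.ndarray:
    """One sub-band of a single-level undecimated wavelet transform.

    ``subband`` is in (x, y, z) physical order; single-slice images use a
    two-letter (x, y) sub-band applied in-plane.  Odd axis lengths are
    symmetrically padded to even (SWT requirement) and cropped back.
    """
    import pywt

    data = img.voxels
    single_slice = data.shape[0] == 1
    axes = (1, 2) if single_slice else (0, 1, 2)
    if len(subband) != len(axes):
        raise ValueError(
            f"subband {subband!r} has {len(subband)} letters for {len(axes)} transform axes")
    # subband is x,y(,z); array axes run z,y,x -> reverse, then map L/H to a/d
    key = "".join({"L": "a", "H": "d"}[ch] for ch in reversed(subband))

    work = data[0] if single_slice else data
    pad = [(0, dim % 2) for dim in work.shape]
    padded = np.pad(work, pad, mode="symmetric")
    coeffs = pywt.swtn(padded, wavelet=wavelet, level=1)[0]
    res = coeffs[key][tuple(slice(0, dim) for dim in work.shape)]
    return res[np.newaxis] if single_slice else res


# ---------------------------------------------------------------------------
# Single-voxel intensity transforms with range restoration
# ---------------------------------------------------------------------------

def _intensity_transform(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "square":
        t = x ** 2
    elif kind == "squareroot":
        t = np.sqrt(np.abs(x))
    elif kind == "logarithm":
        t = np.log(np.abs(x) + 1.0)
    else:  # exponential
        max_abs = np.abs(x).max()
        scale = 1.0 if max_abs <= _EXP_GUARD else _EXP_GUARD / max_abs
        t = np.exp(scale * x)
    # rescale magnitudes to the original image range, restore original sign
    max_orig = np.abs(x).max()
    max_t = np.abs(t).max()
    if max_t == 0.0:
        return np.zeros_like(x)
    sign = np.where(x < 0, -1.0, 1.0)
    return sign * np.abs(t) * (max_orig / max_t)


# ---------------------------------------------------------------------------
# Public surface
# ---------------------------------------------------------------------------

def apply_filter(img: VolumeImage, spec: FilterSpec) -> VolumeImage:
    """Apply one pre-filter; geometry is always preserved."""
    if spec.kind == "original":
        return img.with_voxels(img.voxels.copy())
    if spec.kind == "log":
        return img.with_voxels(_laplacian_of_gaussian(img, spec.sigma_mm))
    if spec.kind == "wavelet":
        return img.with_voxels(_wavelet_subband(img, spec.subband, spec.wavelet))
    return img.with_voxels(_intensity_transform(img.voxels, spec.kind))


def enumerate_filters(kinds: Sequence[str] | None = None,
                      log_sigmas_mm: Iterable[float] = DEFAULT_LOG_SIGMAS_MM,
                      wavelet: str = DEFAULT_WAVELET,
                      ndim: int = 3) -> list[FilterSpec]:
    """The full deterministic filter grid.

    Default 3D grid: 1 original + 5 LoG sigmas + 8 wavelet sub-bands +
    4 intensity transforms = 18 specs.  ``kinds`` restricts which groups
    appear; order is always original, LoG (ascending sigma), wavelet
    (LLL…HHH), square, squareroot, logarithm, exponential.
    """
    kinds = tuple(kinds) if kinds is not None else FILTER_KINDS
    for k in kinds:
        if k not in FILTER_KINDS:
            raise ValueError(f"unknown filter kind {k!r}")
    specs: list[FilterSpec] = []
    if "original" in kinds:
        specs.append(FilterSpec(kind="original"))
    if "log" in kinds:
        specs.extend(FilterSpec(kind="log", sigma_mm=s) for s in sorted(log_sigmas_mm))
    if "wavelet" in kinds:
        for letters in itertools.product("LH", repeat=ndim):
            specs.append(FilterSpec(kind="wavelet", subband="".join(letters), wavelet=wavelet))
    for k in ("square", "squareroot", "logarithm", "exponential"):
        if k in kinds:
            specs.append(FilterSpec(kind=k))
    return specs
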