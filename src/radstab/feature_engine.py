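"""Radiomics feature computation and extraction-grid orchestration.

Five feature classes are computed per (image, mask, configuration):
First Order statistics of the ROI intensity distribution, Shape
descriptors of the ROI geometry (independent of intensities, hence of
normalization and filtering), and three texture classes (GLCM, GLRLM,
GLSZM) over merged texture matrices.  Formulas follow the IBSI consensus
definitions; a few features that are deterministic functions of others
(Compactness1/2, SphericalDisproportion, SumAverage, Homogeneity1/2) or
that are meaningless for single-slice regions (Flatness, LeastAxisLength)
are excluded from the emitted roster.

The processing pipeline per configuration is fixed:
normalize -> filter -> discretize (ROI-only) -> texture matrices ->
features.  Shape features depend only on (mask, roi) and are therefore
identical across every filter; they are still emitted under each
configuration fingerprint so downstream tables stay rectangular.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .filter_bank import FilterSpec, apply_filter
from .preprocessing import NormalizationSpec, apply_normalization
from .texture_core import (DiscretizationSpec, TextureMatrix, discretize,
                           discretize_image, build_glcm, build_glrlm, build_glszm)
from .volumes import MissingROIError, SegmentationMask, VolumeImage

#: features excluded from the emitted roster (redundant with retained
#: features, or undefined for single-slice regions)
EXCLUDED_FEATURES = ("Compactness1", "Compactness2", "SphericalDisproportion",
                     "Flatness", "LeastAxisLength", "SumAverage",
                     "Homogeneity1", "Homogeneity2")

DEFAULT_ROSTER: dict[str, tuple[str, ...]] = {
    "firstorder": ("Mean", "Median", "Entropy", "Energy", "Variance",
                   "Skewness", "Kurtosis", "10Percentile", "90Percentile"),
    "shape": ("Volume", "SurfaceArea", "Sphericity", "SurfaceVolumeRatio",
              "Maximum3DDiameter", "Maximum2DDiameterSlice",
              "MajorAxisLength", "Elongation"),
    "glcm": ("JointEntropy", "JointEnergy", "Idm", "Correlation", "Contrast",
             "JointAverage", "ClusterProminence"),
    "glrlm": ("ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
              "RunPercentage", "GrayLevelVariance"),
    "glszm": ("SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
              "ZonePercentage", "ZoneEntropy"),
}


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """One cell of the processing grid (normalization x filter x bin width x dim)."""

    image_type: str = "synthetic"
    roi: str = "tumor"
    normalization: NormalizationSpec = dataclasses.field(default_factory=NormalizationSpec)
    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    discretization: DiscretizationSpec = dataclasses.field(default_factory=DiscretizationSpec)
    dim: str = "3D"
    roster: Mapping[str, Sequence[str]] | None = None
    exclusions: tuple[str, ...] = EXCLUDED_FEATURES

    def __post_init__(self) -> None:
        if self.dim not in ("2D", "3D"):
            raise ValueError(f"dim must be 2D or 3D, got {self.dim!r}")
        roster = {cls: tuple(names) for cls, names in (self.roster or DEFAULT_ROSTER).items()}
        roster = {cls: tuple(n for n in names if n not in self.exclusions)
                  for cls, names in roster.items()}
        roster = {cls: names for cls, names in roster.items() if names}
        if not roster:
            raise ValueError("feature roster is empty")
        unknown = set(roster) - set(DEFAULT_ROSTER)
        if unknown:
            raise ValueError(f"unknown feature classes {sorted(unknown)}")
        object.__setattr__(self, "roster", roster)

    @property
    def fingerprint(self) -> str:
        return "|".join([self.normalization.fingerprint, self.filter.fingerprint,
                         f"{self.discretization.bin_width:g}", self.dim])


@dataclasses.dataclass(frozen=True)
class FeatureRecord:
    """One extracted feature value; NaN value means flagged-missing."""

    subject_id: str
    timepoint: str
    image_type: str
    roi: str
    normalization: str
    filter: str
    bin_width: float
    dim: str
    feature_class: str
    feature: str
    value: float


# ---------------------------------------------------------------------------
# First Order
# ---------------------------------------------------------------------------

def first_order_features(roi_values: np.ndarray,
                         bin_width: float | DiscretizationSpec = 15.0) -> dict[str, float]:
    """First-order statistics of the ROI intensity distribution.

    Entropy is computed on the fixed-bin-width discretized levels with
    log base 2 and the 0*log0 = 0 convention.  Variance/Skewness/Kurtosis
    use population moments; Kurtosis is non-excess (a normal
    distribution scores 3).  Percentiles interpolate linearly between
    order statistics.
    """
    x = np.asarray(roi_values, dtype=np.float64).ravel()
    if x.size == 0:
        raise MissingROIError("empty ROI")
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    levels, _ = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(np.float64)
    p = p[p > 0] / x.size
    return {
        "Mean": mean,
        "Median": float(np.median(x)),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Energy": float((x ** 2).sum()),
        "Variance": m2,
        "Skewness": 0.0 if m2 == 0 else m3 / m2 ** 1.5,
        "Kurtosis": 0.0 if m2 == 0 else m4 / m2 ** 2,
        "10Percentile": float(np.percentile(x, 10)),
        "90Percentile": float(np.percentile(x, 90)),
    }


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def _max_pairwise_distance(coords: np.ndarray) -> float:
    """Largest distance between points, via convex hull when it helps."""
    if len(coords) < 2:
        return 0.0
    pts = coords
    if len(pts) > 500:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:  # degenerate (coplanar/collinear) clouds
            pts = np.unique(pts, axis=0)
    return float(pdist(pts).max())


def shape_features(mask: SegmentationMask, roi: str,
                   spacing: tuple[float, float, float] | None = None) -> dict[str, float]:
    """Geometry descriptors of one ROI.

    Volume is voxel-count volume; SurfaceArea counts exposed voxel
    faces; Sphericity = pi^(1/3) (6V)^(2/3) / A; diameters are measured
    between voxel centres; axis lengths derive from the eigenvalues of
    the physical-coordinate covariance (4 * sqrt(lambda)).
    """
    sx, sy, sz = spacing or mask.spacing
    roi_mask = mask.roi_mask(roi)
    n = int(roi_mask.sum())
    voxel_volume = sx * sy * sz
    volume = n * voxel_volume

    # exposed faces per axis: transitions along the axis incl. grid border
    area = 0.0
    for ax, face_area in ((0, sx * sy), (1, sx * sz), (2, sy * sz)):
        padded = np.pad(roi_mask, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        area += float(np.abs(np.diff(padded.astype(np.int8), axis=ax)).sum()) * face_area

    zi, yi, xi = np.nonzero(roi_mask)
    coords = np.column_stack([xi * sx, yi * sy, zi * sz]).astype(np.float64)
    max3d = _max_pairwise_distance(coords)
    max2d = 0.0
    for z in np.unique(zi):
        sel = zi == z
        max2d = max(max2d, _max_pairwise_distance(coords[sel][:, :2]))

    centered = coords - coords.mean(axis=0)
    eig = np.sort(np.linalg.eigvalsh(centered.T @ centered / n))[::-1]
    eig = np.clip(eig, 0.0, None)
    major = 4.0 * float(np.sqrt(eig[0]))
    elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else np.nan

    return {
        "Volume": volume,
        "SurfaceArea": area,
        "Sphericity": float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area),
        "SurfaceVolumeRatio": area / volume,
        "Maximum3DDiameter": max3d,
        "Maximum2DDiameterSlice": max2d,
        "MajorAxisLength": major,
        "Elongation": elong,
    }


# ---------------------------------------------------------------------------
# Texture feature classes
# ---------------------------------------------------------------------------

def _require(matrix: TextureMatrix, kind: str, normalized: bool | None = None) -> np.ndarray:
    if matrix.kind != kind:
        raise ValueError(f"expected a {kind} matrix, got {matrix.kind}")
    if normalized is not None and matrix.normalized != normalized:
        state = "normalized" if normalized else "count"
        raise ValueError(f"{kind} features need a {state} matrix")
    m = matrix.matrix
    if m.sum() == 0:
        raise MissingROIError(f"empty {kind} matrix")
    return m


def glcm_features(matrix: TextureMatrix, include_internal: bool = False) -> dict[str, float]:
    """GLCM statistics on a normalized, merged co-occurrence matrix.

    Correlation of a degenerate (zero grey-level variance) matrix is
    flagged missing (NaN).  ``include_internal`` additionally returns
    SumAverage, which equals 2 * JointAverage for symmetric matrices and
    is excluded from the emitted roster for that reason.
    """
    p = _require(matrix, "GLCM", normalized=True)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    nz = p > 0
    out = {
        "JointEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((p * (ii + jj - mu_x - mu_y) ** 4).sum()),
    }
    denom = np.sqrt(var_x * var_y)
    out["Correlation"] = np.nan if denom == 0 else \
        float(((p * ii * jj).sum() - mu_x * mu_y) / denom)
    if include_internal:
        out["SumAverage"] = float((p * (ii + jj)).sum())
    return out


def glrlm_features(matrix: TextureMatrix) -> dict[str, float]:
    """GLRLM statistics on a merged run-length count matrix."""
    r = _require(matrix, "GLRLM")
    nr = r.sum()
    lengths = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    levels = np.arange(1, r.shape[0] + 1, dtype=np.float64)
    p = r / nr
    p_level = p.sum(axis=1)
    mu = float((levels * p_level).sum())
    return {
        "ShortRunEmphasis": float((r / lengths ** 2).sum() / nr),
        "LongRunEmphasis": float((r * lengths ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((r.sum(axis=1) ** 2).sum() / nr),
        # fraction of voxel-direction slots that start a run; merged
        # accumulation makes sum(r*l) = |ROI| * n_directions
        "RunPercentage": float(nr / (r * lengths).sum()),
        "GrayLevelVariance": float(((levels - mu) ** 2 * p_level).sum()),
    }


def glszm_features(matrix: TextureMatrix) -> dict[str, float]:
    """GLSZM statistics on a zone-size count matrix."""
    s = _require(matrix, "GLSZM")
    ns = s.sum()
    sizes = np.arange(1, s.shape[1] + 1, dtype=np.float64)
    nz = s > 0
    p = s / ns
    return {
        "SmallAreaEmphasis": float((s / sizes ** 2).sum() / ns),
        "LargeAreaEmphasis": float((s * sizes ** 2).sum() / ns),
        "GrayLevelNonUniformity": float((s.sum(axis=1) ** 2).sum() / ns),
        "ZonePercentage": float(ns / (s * sizes).sum()),
        "ZoneEntropy": float(-(p[nz] * np.log2(p[nz])).sum()),
    }


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract(img: VolumeImage, mask: SegmentationMask, config: ExtractionConfig,
            subject_id: str = "s0", timepoint: str = "test") -> list[FeatureRecord]:
    """Run the full pipeline for one (image, mask, config) cell.

    Stages run in fixed order: normalize -> filter -> discretize ->
    matrices -> features.  A feature whose computation fails on a
    degenerate ROI is emitted with a NaN value rather than silently
    dropped, so the output grid is always complete.
    """
    normalized = apply_normalization(img, mask, config.normalization)
    filtered = apply_filter(normalized, config.filter)
    return extract_from_filtered(filtered, mask, config, subject_id, timepoint)


def extract_from_filtered(filtered: VolumeImage, mask: SegmentationMask,
                          config: ExtractionConfig, subject_id: str = "s0",
                          timepoint: str = "test") -> list[FeatureRecord]:
    """Feature stage of :func:`extract`, for callers that cache the
    normalized/filtered image across bin widths and dimensionalities."""
    records: list[FeatureRecord] = []

    def emit(cls: str, values: Mapping[str, float]) -> None:
        for name in config.roster.get(cls, ()):
            v = values.get(name, np.nan)
            records.append(FeatureRecord(
                subject_id=subject_id, timepoint=timepoint,
                image_type=config.image_type, roi=config.roi,
                normalization=config.normalization.fingerprint,
                filter=config.filter.fingerprint,
                bin_width=config.discretization.bin_width, dim=config.dim,
                feature_class=cls, feature=name,
                value=float(v) if np.isfinite(v) else np.nan))

    roi_mask = mask.roi_mask(config.roi)
    values = filtered.voxels[roi_mask]

    if "firstorder" in config.roster:
        emit("firstorder", first_order_features(values, config.discretization))
    if "shape" in config.roster:
        emit("shape", shape_features(mask, config.roi))

    texture_classes = [c for c in ("glcm", "glrlm", "glszm") if c in config.roster]
    if texture_classes:
        level_grid, _ = discretize_image(filtered.voxels, roi_mask, config.discretization)
        builders = {"glcm": lambda: glcm_features(build_glcm(level_grid, dim=config.dim)),
                    "glrlm": lambda: glrlm_features(build_glrlm(level_grid, dim=config.dim)),
                    "glszm": lambda: glszm_features(build_glszm(level_grid, dim=config.dim))}
        for cls in texture_classes:
            try:
                emit(cls, builders[cls]())
            except MissingROIError:
                emit(cls, {})
    return records


class FeatureTable:
    """Long-format store of extracted feature values.

    Thin wrapper around a pandas DataFrame with the canonical column
    set; the key (subject, timepoint, roi, image_type, config
    fingerprint, class, feature) is unique.
    """

    COLUMNS = ("subject_id", "timepoint", "image_type", "roi", "normalization",
               "filter", "bin_width", "dim", "feature_class", "feature", "value")
    KEY = [c for c in COLUMNS if c != "value"]

    def __init__(self, df: pd.DataFrame, provenance: Mapping[str, object] | None = None):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if df.duplicated(subset=self.KEY).any():
            raise ValueError("duplicate feature keys in table")
        self.df = df
        self.provenance = dict(provenance or {})

    @classmethod
    def from_records(cls, records: Iterable[FeatureRecord],
                     provenance: Mapping[str, object] | None = None) -> "FeatureTable":
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        return cls(df, provenance)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls(pd.read_csv(path, dtype={"subject_id": str, "timepoint": str}))

    def __len__(self) -> int:
        return len(self.df)
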