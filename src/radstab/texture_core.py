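"""Grey-level discretization and texture-matrix construction.

Texture features are statistics over matrices that summarize the spatial
arrangement of discretized grey levels inside a region of interest:

* **GLCM** — co-occurrence counts of level pairs at a fixed voxel offset;
* **GLRLM** — counts of maximal same-level runs by level and length;
* **GLSZM** — counts of connected same-level zones by level and size.

Discretization uses a fixed bin *width* anchored at the ROI minimum
(level(x) = floor((x - min)/w) + 1), computed only from intensities
inside the ROI.  Matrices are built either in 3D (13 unique directions,
26-connected zones) or per-slice 2D (4 in-plane directions, 8-connected
zones) and merged by summation over directions and slices before any
normalization, so each configuration yields a single matrix.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import ndimage

from .volumes import MissingROIError

#: the study's bin-width grid
STUDY_BIN_WIDTHS = (10.0, 15.0, 20.0, 40.0)

# unique direction offsets (dz, dy, dx): 13 in 3D (half of the 26
# neighbours), 4 in-plane for per-slice 2D analysis
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d[0] > 0 or (d[0] == 0 and (d[1] > 0 or (d[1] == 0 and d[2] > 0))))
)
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = ((0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1))


@dataclasses.dataclass(frozen=True)
class DiscretizationSpec:
    """Fixed-bin-width discretization choice.

    ``mode`` selects the bin anchoring: ``"roi_min"`` (default) anchors
    the first bin at the ROI minimum; ``"aligned"`` places bin edges at
    integer multiples of the width, as some toolkits do.  Both map the
    ROI minimum to level 1.
    """

    bin_width: float = 15.0
    mode: str = "roi_min"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mode not in ("roi_min", "aligned"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")


@dataclasses.dataclass(frozen=True)
class TextureMatrix:
    """One merged texture matrix.

    ``matrix`` rows index grey level 1..Ng; columns index the paired
    level (GLCM), run length 1..Lmax (GLRLM) or zone size 1..Zmax
    (GLSZM).  ``n_directions`` records how many direction offsets were
    merged (needed for per-voxel rates such as RunPercentage).
    """

    kind: str
    matrix: np.ndarray
    ng: int
    dim: str
    n_directions: int = 1
    aggregation: str = "merged"
    normalized: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or (m < 0).any():
            raise ValueError("texture matrix must be 2D with non-negative entries")
        if self.kind not in ("GLCM", "GLRLM", "GLSZM"):
            raise ValueError(f"unknown texture matrix kind {self.kind!r}")
        if self.dim not in ("2D", "3D"):
            raise ValueError(f"dim must be 2D or 3D, got {self.dim!r}")


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(values: np.ndarray, spec: DiscretizationSpec | float) -> tuple[np.ndarray, int]:
    """Map ROI intensities to integer grey levels 1..Ng.

    Default anchoring: ``level(x) = floor((x - min)/w) + 1`` with
    ``min`` the ROI minimum, so the number of levels never exceeds
    ``floor(range/w) + 1``.  In ``aligned`` mode bins sit at multiples
    of ``w`` (``floor(x/w) - floor(min/w) + 1``), which can add one
    extra level when the ROI range straddles an edge.
    """
    if not isinstance(spec, DiscretizationSpec):
        spec = DiscretizationSpec(bin_width=float(spec))
    w = spec.bin_width
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise MissingROIError("cannot discretize an empty ROI")
    if spec.mode == "aligned":
        levels = (np.floor(values / w) - np.floor(values.min() / w)).astype(np.int64) + 1
    else:
        levels = np.floor((values - values.min()) / w).astype(np.int64) + 1
    return levels, int(levels.max())


def discretize_image(voxels: np.ndarray, roi: np.ndarray,
                     spec: DiscretizationSpec | float) -> tuple[np.ndarray, int]:
    """Grid variant: level grid (0 outside the ROI) plus Ng."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise MissingROIError("cannot discretize an empty ROI")
    levels, ng = discretize(np.asarray(voxels, dtype=np.float64)[roi], spec)
    grid = np.zeros(roi.shape, dtype=np.int64)
    grid[roi] = levels
    return grid, ng


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _directions(dim: str, ndim_data: int = 3) -> tuple[tuple[int, int, int], ...]:
    if dim == "3D":
        return DIRECTIONS_3D
    if dim == "2D":
        return DIRECTIONS_2D
    raise ValueError(f"dim must be '2D' or '3D', got {dim!r}")


def _check_levels(level_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    grid = np.asarray(level_grid)
    if grid.ndim == 2:  # allow single-slice input given as 2D
        grid = grid[np.newaxis]
    if grid.ndim != 3:
        raise ValueError("level grid must be 2D or 3D")
    if grid.min() < 0:
        raise ValueError("levels must be 0 (outside ROI) or 1..Ng")
    roi = grid > 0
    if not roi.any():
        raise MissingROIError("level grid has no ROI voxels")
    return grid, roi, int(grid.max())


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill) -> np.ndarray:
    """Array whose value at v is arr[v + offset]; out-of-grid -> fill."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for ax, d in enumerate(offset):
        n = arr.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src.append(slice(d, n))
            dst.append(slice(0, n - d))
        else:
            src.append(slice(0, n + d))
            dst.append(slice(-d, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def build_glcm(level_grid: np.ndarray, dim: str = "3D", distance: int = 1,
               symmetric: bool = True, normalize: bool = True,
               directions: tuple[tuple[int, int, int], ...] | None = None) -> TextureMatrix:
    """Grey-level co-occurrence matrix merged over directions (and slices).

    ``level_grid`` holds levels 1..Ng inside the ROI and 0 outside.  A
    pair is counted when both voxels of the offset lie inside the ROI;
    symmetric accumulation counts each pair in both orders.
    ``directions`` overrides the default direction set of ``dim``.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    grid, roi, ng = _check_levels(level_grid)
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in (directions if directions is not None else _directions(dim)):
        offset = tuple(distance * c for c in d)
        neigh = _shift(grid, offset, fill=0)
        both = roi & (neigh > 0)
        if not both.any():
            continue
        np.add.at(counts, (grid[both] - 1, neigh[both] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if normalize:
        if total == 0:
            raise MissingROIError("no co-occurring pairs in ROI")
        counts = counts / total
    n_dirs = len(directions) if directions is not None else len(_directions(dim))
    return TextureMatrix(kind="GLCM", matrix=counts, ng=ng, dim=dim,
                         n_directions=n_dirs, normalized=normalize)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def build_glrlm(level_grid: np.ndarray, dim: str = "3D",
                directions: tuple[tuple[int, int, int], ...] | None = None) -> TextureMatrix:
    """Grey-level run-length matrix merged over directions (and slices).

    A run is a maximal straight sequence of ROI voxels sharing one level
    along one direction; every ROI voxel belongs to exactly one run per
    direction, so sum(r(i,l) * l) = |ROI| * n_directions.
    """
    grid, roi, ng = _check_levels(level_grid)
    dirs = directions if directions is not None else _directions(dim)
    max_len = max(grid.shape)
    counts = np.zeros((ng, max_len), dtype=np.float64)
    for d in dirs:
        neigh = _shift(grid, d, fill=0)
        cont = roi & (neigh == grid) & (neigh > 0)  # run continues at v+d
        # propagate remaining-run-length backwards along the direction
        run = np.where(roi & ~cont, 1, 0)
        for _ in range(max_len):
            ahead = _shift(run, d, fill=0)
            new = np.where(cont & (ahead > 0), ahead + 1, run)
            if np.array_equal(new, run):
                break
            run = new
        back = _shift(grid, tuple(-c for c in d), fill=0)
        starts = roi & ~(back == grid)  # no same-level ROI voxel behind
        np.add.at(counts, (grid[starts] - 1, run[starts] - 1), 1.0)
    used = max(1, int(np.max(np.nonzero(counts.sum(axis=0))[0])) + 1) if counts.any() else 1
    return TextureMatrix(kind="GLRLM", matrix=counts[:, :used], ng=ng, dim=dim,
                         n_directions=len(dirs))


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def build_glszm(level_grid: np.ndarray, dim: str = "3D") -> TextureMatrix:
    """Grey-level size-zone matrix.

    Zones are connected components of equal level — 26-connected in 3D,
    8-connected within each slice in 2D.  Every ROI voxel belongs to
    exactly one zone, so sum(s(i,z) * z) = |ROI|.
    """
    grid, roi, ng = _check_levels(level_grid)
    if dim == "3D":
        structure = np.ones((3, 3, 3), dtype=bool)
    elif dim == "2D":  # 8-connectivity within each slice, no cross-slice links
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[1, :, :] = True
    else:
        raise ValueError(f"dim must be '2D' or '3D', got {dim!r}")
    zones: list[tuple[int, int]] = []  # (level, size)
    for level in range(1, ng + 1):
        sel = grid == level
        if not sel.any():
            continue
        labelled, n = ndimage.label(sel, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        zones.extend((level, int(z)) for z in sizes)
    max_size = max(z for _, z in zones)
    counts = np.zeros((ng, max_size), dtype=np.float64)
    for level, size in zones:
        counts[level - 1, size - 1] += 1.0
    return TextureMatrix(kind="GLSZM", matrix=counts, ng=ng, dim=dim, n_directions=1)
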