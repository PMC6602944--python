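"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available —
exhaustive pair/run/zone enumeration, full-kernel convolution, raw
sums-of-squares — deliberately sharing no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_glcm(grid: np.ndarray, directions, symmetric: bool = True) -> np.ndarray:
    """Exhaustive voxel-pair enumeration co-occurrence counts."""
    grid = np.asarray(grid)
    ng = int(grid.max())
    counts = np.zeros((ng, ng))
    for v in np.ndindex(grid.shape):
        if grid[v] == 0:
            continue
        for d in directions:
            w = tuple(a + b for a, b in zip(v, d))
            if any(c < 0 or c >= s for c, s in zip(w, grid.shape)):
                continue
            if grid[w] == 0:
                continue
            counts[grid[v] - 1, grid[w] - 1] += 1
            if symmetric:
                counts[grid[w] - 1, grid[v] - 1] += 1
    return counts


def brute_glrlm(grid: np.ndarray, directions) -> dict[tuple[int, int], int]:
    """Maximal same-level run scanner; returns {(level, length): count}."""
    grid = np.asarray(grid)
    runs: dict[tuple[int, int], int] = {}

    def inside(v):
        return all(0 <= c < s for c, s in zip(v, grid.shape))

    for d in directions:
        for v in np.ndindex(grid.shape):
            if grid[v] == 0:
                continue
            prev = tuple(a - b for a, b in zip(v, d))
            if inside(prev) and grid[prev] == grid[v]:
                continue  # not the start of a maximal run
            length = 0
            w = v
            while inside(w) and grid[w] == grid[v]:
                length += 1
                w = tuple(a + b for a, b in zip(w, d))
            key = (int(grid[v]), length)
            runs[key] = runs.get(key, 0) + 1
    return runs


def brute_glszm(grid: np.ndarray, connectivity: str = "26") -> dict[tuple[int, int], int]:
    """Flood-fill zone scanner; returns {(level, size): count}.

    ``connectivity`` "26" links all 3D neighbours, "8" only in-plane
    (slice-wise) neighbours.
    """
    grid = np.asarray(grid)
    if connectivity == "26":
        offsets = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    else:
        offsets = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                   if (dy, dx) != (0, 0)]
    seen = np.zeros(grid.shape, dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for v in np.ndindex(grid.shape):
        if grid[v] == 0 or seen[v]:
            continue
        stack, size = [v], 0
        seen[v] = True
        while stack:
            u = stack.pop()
            size += 1
            for d in offsets:
                w = tuple(a + b for a, b in zip(u, d))
                if any(c < 0 or c >= s for c, s in zip(w, grid.shape)):
                    continue
                if not seen[w] and grid[w] == grid[v]:
                    seen[w] = True
                    stack.append(w)
        key = (int(grid[v]), size)
        zones[key] = zones.get(key, 0) + 1
    return zones


def runs_to_matrix(runs: dict[tuple[int, int], int], ng: int) -> np.ndarray:
    max_len = max(l for _, l in runs)
    m = np.zeros((ng, max_len))
    for (level, length), c in runs.items():
        m[level - 1, length - 1] = c
    return m


def brute_log(voxels: np.ndarray, spacing_xyz, sigma_mm: float) -> np.ndarray:
    """Full-3D-kernel Laplacian-of-Gaussian convolution.

    Builds the complete separable-product kernel explicitly and applies
    it by direct shifted-sum convolution over symmetric padding.
    """
    from radstab.filter_bank import log_kernels_1d

    sx, sy, sz = spacing_xyz
    spacing_zyx = (sz, sy, sx)
    kernels = [log_kernels_1d(sigma_mm / s) for s in spacing_zyx]
    radii = [(k[0].size - 1) // 2 for k in kernels]
    full = np.zeros(tuple(2 * r + 1 for r in radii))
    for deriv_ax in range(3):
        parts = [kernels[ax][1] if ax == deriv_ax else kernels[ax][0] for ax in range(3)]
        term = np.einsum("i,j,k->ijk", *parts) / spacing_zyx[deriv_ax] ** 2
        full += term
    padded = np.pad(voxels, [(r, r) for r in radii], mode="symmetric")
    out = np.zeros(voxels.shape)
    for off in np.ndindex(full.shape):
        sl = tuple(slice(o, o + s) for o, s in zip(off, voxels.shape))
        out += full[off] * padded[sl]
    return out


def icc_oneway_direct(pairs: np.ndarray) -> tuple[float, float, float]:
    """(ICC, BMS, WMS) from the raw sums-of-squares decomposition."""
    x = np.asarray(pairs, dtype=float)
    n = x.shape[0]
    grand = x.mean()
    sst = ((x - grand) ** 2).sum()
    ssw = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum()
    ssb = sst - ssw
    bms = ssb / (n - 1)
    wms = ssw / n
    return (bms - wms) / (bms + wms), bms, wms
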