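"""Transition pathways between metastable states of a density landscape.

The most probable route between activation states is computed in three
steps on an activity-annotated 2D density landscape:

1. **Peaks** — strict local maxima of the Gaussian-smoothed density
   (8-neighborhood), above a relative density floor, de-duplicated by a
   minimum separation.  Each peak is a metastable state.
2. **Bottleneck paths** — every pair of peaks is joined by the
   8-connected grid path minimising the highest barrier crossed, where
   the barrier of a cell is -log(density + eps).  This minimax ("widest
   path") criterion is the saddle-crossing reading of a minimum-density
   path: the route over the lowest pass, not the shortest or the
   lowest-integral one.
3. **Activity ordering** — each peak is assigned a basin activity (the
   count-weighted mean predicted activity in a small Chebyshev
   neighborhood) and peaks are chained in ascending basin activity: the
   inactive-to-active transition pathway.

The bottleneck search runs a union-find sweep over cells sorted by
barrier (exact minimax value), then extracts a shortest admissible path
with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    EmptyResultError,
    InsufficientStatesError,
    NoPathError,
    OutOfRangeError,
    UndefinedActivityError,
)
from .landscape import DensityLandscape

__all__ = [
    "Peak",
    "GridPath",
    "TransitionPath",
    "find_peaks",
    "barrier_grid",
    "bottleneck_path",
    "basin_activity",
    "build_transition_pathway",
]

# 8-connected neighbor offsets, in lexicographic order for determinism
_NEIGHBORS = tuple(
    (di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
)


@dataclass(frozen=True)
class Peak:
    """A density peak: a metastable state of the landscape."""

    index: tuple[int, int]
    x: float
    y: float
    density: float              # smoothed density at the peak
    activity: float | None = None  # basin mean activity, filled by the pathway builder


@dataclass
class GridPath:
    """An 8-connected cell path between two peaks with its bottleneck.

    ``bottleneck`` is the maximum barrier -log(density + eps) along the
    path, endpoints included; it is therefore never below the barrier at
    either endpoint.
    """

    cells: list[tuple[int, int]]
    bottleneck: float

    @property
    def length(self) -> int:
        return len(self.cells)


@dataclass
class TransitionPath:
    """Peaks in ascending basin activity joined by bottleneck paths."""

    peaks: list[Peak]
    segments: list[GridPath]
    activities: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not self.activities:
            self.activities = [p.activity for p in self.peaks]
        diffs = np.diff(self.activities)
        assert np.all(diffs >= -1e-12), "pathway activities must be non-decreasing"

    def to_dict(self) -> dict:
        return {
            "peaks": [
                {"cell": list(p.index), "x": p.x, "y": p.y,
                 "density": p.density, "activity": p.activity}
                for p in self.peaks
            ],
            "activities": [float(a) for a in self.activities],
            "segments": [
                {"cells": [list(c) for c in s.cells], "bottleneck": s.bottleneck}
                for s in self.segments
            ],
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def find_peaks(
    landscape: DensityLandscape,
    smoothing_sigma: float = 1.0,
    min_rel_density: float = 0.05,
    min_separation: int = 2,
) -> list[Peak]:
    """Strict local maxima of the Gaussian-smoothed density.

    A cell is a peak if its smoothed density exceeds all 8 neighbors
    (off-grid neighbors count as -inf) and is at least
    ``min_rel_density`` times the global smoothed maximum.  Peaks within
    Chebyshev distance < ``min_separation`` of a denser peak are merged
    into it.  Returned in descending density, ties by cell index.
    """
    if landscape.counts.size == 0:
        raise EmptyResultError("empty landscape")
    smoothed = gaussian_filter(landscape.density, sigma=smoothing_sigma, mode="constant")
    nx, ny = smoothed.shape
    padded = np.full((nx + 2, ny + 2), -np.inf)
    padded[1:-1, 1:-1] = smoothed
    strict_max = np.ones((nx, ny), dtype=bool)
    for di, dj in _NEIGHBORS:
        strict_max &= smoothed > padded[1 + di : 1 + di + nx, 1 + dj : 1 + dj + ny]
    threshold = min_rel_density * smoothed.max()
    strict_max &= smoothed >= threshold
    candidates = sorted(
        ((float(smoothed[i, j]), (int(i), int(j)))
         for i, j in zip(*np.nonzero(strict_max))),
        key=lambda t: (-t[0], t[1]),
    )
    kept: list[tuple[float, tuple[int, int]]] = []
    for dens, (i, j) in candidates:
        if all(max(abs(i - ki), abs(j - kj)) >= min_separation for _, (ki, kj) in kept):
            kept.append((dens, (i, j)))
    if not kept:
        warnings.warn("no density peak above threshold", stacklevel=2)
    return [
        Peak(index=(i, j), x=float(landscape.x_centers[i]),
             y=float(landscape.y_centers[j]), density=dens)
        for dens, (i, j) in kept
    ]


def default_epsilon(landscape: DensityLandscape) -> float:
    """Density floor: half a count spread over one cell, 1/(2*N*cell_area).

    Keeps -log finite on empty cells while ranking them as the worst
    barriers on the grid.
    """
    dx = float(np.diff(landscape.x_edges).mean())
    dy = float(np.diff(landscape.y_edges).mean())
    return 1.0 / (2.0 * max(landscape.n_total, 1) * dx * dy)


def barrier_grid(landscape: DensityLandscape, epsilon: float | None = None) -> np.ndarray:
    """Per-cell barrier height -log(density + eps)."""
    if epsilon is None:
        epsilon = default_epsilon(landscape)
    with np.errstate(divide="ignore"):
        return -np.log(landscape.density + epsilon)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def minimax_barrier(barrier: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Exact minimax bottleneck between two cells on an 8-connected grid.

    Cells are activated in increasing barrier order; the bottleneck is
    the activation level at which a and b first become connected.
    Infinite-barrier cells are never activated.
    """
    nx, ny = barrier.shape
    flat = lambda i, j: i * ny + j  # noqa: E731
    order = sorted(
        ((barrier[i, j], (i, j)) for i in range(nx) for j in range(ny)
         if np.isfinite(barrier[i, j])),
        key=lambda t: (t[0], t[1]),
    )
    uf = _UnionFind(nx * ny)
    active = np.zeros((nx, ny), dtype=bool)
    for level, (i, j) in order:
        active[i, j] = True
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny and active[ni, nj]:
                uf.union(flat(i, j), flat(ni, nj))
        if active[a] and active[b] and uf.find(flat(*a)) == uf.find(flat(*b)):
            return float(level)
    raise NoPathError(f"cells {a} and {b} are not connected by finite-barrier cells")


def bottleneck_path(
    landscape: DensityLandscape,
    a: Peak | tuple[int, int],
    b: Peak | tuple[int, int],
    epsilon: float | None = None,
) -> GridPath:
    """Minimum-density (minimax-barrier) path between two peaks.

    Among all 8-connected paths the result minimises the maximum barrier
    -log(density + eps); ties are broken by fewest cells, then by
    lexicographically smallest cell sequence.
    """
    ca = a.index if isinstance(a, Peak) else tuple(a)
    cb = b.index if isinstance(b, Peak) else tuple(b)
    if ca == cb:
        raise OutOfRangeError(f"source and target are the same cell {ca}")
    barrier = barrier_grid(landscape, epsilon)
    bott = minimax_barrier(barrier, ca, cb)

    admissible = barrier <= bott
    nx, ny = barrier.shape
    # BFS from the target gives distance-to-target on the admissible set
    dist = np.full((nx, ny), -1, dtype=int)
    dist[cb] = 0
    queue = [cb]
    while queue:
        nxt = []
        for i, j in queue:
            for di, dj in _NEIGHBORS:
                ni, nj = i + di, j + dj
                if (0 <= ni < nx and 0 <= nj < ny and admissible[ni, nj]
                        and dist[ni, nj] < 0):
                    dist[ni, nj] = dist[i, j] + 1
                    nxt.append((ni, nj))
        queue = nxt
    if dist[ca] < 0:
        raise NoPathError(f"cells {ca} and {cb} disconnected at bottleneck level")

    # greedy forward walk: always step to the lexicographically smallest
    # neighbor that strictly decreases distance-to-target -> among all
    # shortest admissible paths this is the lexicographically smallest
    cells = [ca]
    cur = ca
    while cur != cb:
        i, j = cur
        nxt = min(
            (i + di, j + dj) for di, dj in _NEIGHBORS
            if 0 <= i + di < nx and 0 <= j + dj < ny
            and dist[i + di, j + dj] == dist[i, j] - 1
        )
        cells.append(nxt)
        cur = nxt
    return GridPath(cells=cells, bottleneck=float(max(barrier[c] for c in cells)))


def basin_activity(
    landscape: DensityLandscape, peak: Peak | tuple[int, int], radius: int = 2
) -> float:
    """Count-weighted mean predicted activity within a Chebyshev
    neighborhood of the peak (radius 0 = the peak cell itself)."""
    ci, cj = peak.index if isinstance(peak, Peak) else tuple(peak)
    nx, ny = landscape.counts.shape
    lo_i, hi_i = max(0, ci - radius), min(nx, ci + radius + 1)
    lo_j, hi_j = max(0, cj - radius), min(ny, cj + radius + 1)
    counts = landscape.counts[lo_i:hi_i, lo_j:hi_j]
    acts = landscape.activity_mean[lo_i:hi_i, lo_j:hi_j]
    occupied = counts > 0
    if not np.any(occupied):
        raise UndefinedActivityError(
            f"no occupied cells within radius {radius} of cell ({ci},{cj})"
        )
    return float(np.sum(counts[occupied] * acts[occupied]) / np.sum(counts[occupied]))


def build_transition_pathway(
    landscape: DensityLandscape,
    smoothing_sigma: float = 1.0,
    min_rel_density: float = 0.05,
    min_separation: int = 2,
    basin_radius: int = 2,
    epsilon: float | None = None,
) -> TransitionPath:
    """The full three-step algorithm: peaks, activity ordering, bottleneck
    connections.  Peaks with equal basin activity are ordered by
    descending density (then cell index)."""
    peaks = find_peaks(landscape, smoothing_sigma, min_rel_density, min_separation)
    if len(peaks) < 2:
        raise InsufficientStatesError(
            f"found {len(peaks)} peak(s); at least 2 states are needed for a pathway"
        )
    annotated = [
        Peak(index=p.index, x=p.x, y=p.y, density=p.density,
             activity=basin_activity(landscape, p, radius=basin_radius))
        for p in peaks
    ]
    ordered = sorted(annotated, key=lambda p: (p.activity, -p.density, p.index))
    segments = [
        bottleneck_path(landscape, u, v, epsilon=epsilon)
        for u, v in zip(ordered, ordered[1:])
    ]
    return TransitionPath(peaks=ordered, segments=segments)
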