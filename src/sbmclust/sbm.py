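"""Original Space Breakdown Method over a dense N-dimensional count array.

SBM is a deterministic grid-based clustering algorithm for spike-sorting
feature spaces.  It proceeds in five sequential stages:

1. *normalisation* — min-max scale every feature into ``[0, PN]``;
2. *chunkification* — floor each point into one of ``PN**N`` hypercubic
   cells ("chunks") and count the points per chunk;
3. *centroid search* — chunks whose count exceeds a minimum threshold and
   strictly exceeds every (diagonal-inclusive) neighbour become cluster
   centroid candidates;
4. *expansion* — a breadth-first search grows each candidate outward over
   occupied chunks along non-increasing counts, merging candidates that
   are swallowed by an earlier expansion;
5. *dechunkification* — every point inherits the label of its chunk.

Labelling convention of the original algorithm: clusters are numbered from
1 and noise (points in chunks never claimed by an expansion) is 0.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .exceptions import (
    CellBudgetError,
    ContractError,
    DegenerateFeatureError,
    ParameterError,
)

#: Noise label of the original (array) SBM.
NOISE_LABEL_SBM = 0

#: Default minimum point count for a chunk to become a centroid candidate.
#: Guards against conglomerations of isolated noise points forming clusters.
DEFAULT_THRESHOLD = 5

#: Refuse dense arrays larger than this many cells (the dense structure is
#: exponential in dimensionality; the graph variant in :mod:`sbmclust.isbm`
#: has no such limit because it stores only occupied chunks).
DEFAULT_CELL_BUDGET = 50_000_000


@dataclass(frozen=True)
class SBMParams:
    """Parameters of an SBM/ISBM fit.

    Parameters
    ----------
    pn : int
        Partitioning number: partitions per feature (>= 2).  Under ISBM
        this is the partition count of the highest-variance feature.
    threshold : int
        Minimum point count (exclusive) for centroid candidacy (>= 0).
    """

    pn: int
    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self):
        if int(self.pn) != self.pn or self.pn < 2:
            raise ParameterError(f"pn must be an integer >= 2, got {self.pn}")
        if int(self.threshold) != self.threshold or self.threshold < 0:
            raise ParameterError(
                f"threshold must be a non-negative integer, got {self.threshold}"
            )


@dataclass
class ClusteringResult:
    """Outcome of a clustering fit.

    Attributes
    ----------
    labels : ndarray of int, shape (n,)
        Per-point cluster labels in the convention recorded by
        ``noise_label``: the original SBM numbers clusters from 1 with
        noise 0; ISBM numbers from 0 with noise -1.
    noise_label : int
        The reserved noise label.
    n_clusters : int
        Number of distinct non-noise labels.
    n_noise : int
        Number of noise-labelled points.
    chunk_stats : dict
        Occupied-chunk / total-cell / centroid-count accounting.
    """

    labels: np.ndarray
    noise_label: int
    n_clusters: int = 0
    n_noise: int = 0
    chunk_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        non_noise = self.labels[self.labels != self.noise_label]
        self.n_clusters = int(np.unique(non_noise).size)
        self.n_noise = int(self.labels.size - non_noise.size)


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ParameterError(f"expected an (n, N) matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ParameterError("input contains non-finite values")
    return X


def minmax_normalise(X, pn: int) -> np.ndarray:
    """Min-max scale every feature of ``X`` into ``[0, pn]``.

    Each feature d is mapped by ``x' = pn * (x - min_d) / (max_d - min_d)``.

    Raises
    ------
    DegenerateFeatureError
        If a feature is constant (``max == min``), naming the column.
    """
    X = _as_matrix(X)
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    for d in np.flatnonzero(span == 0):
        raise DegenerateFeatureError(int(d))
    return pn * (X - lo) / span


def chunk_indices(Xn: np.ndarray, pv) -> np.ndarray:
    """Floor normalised coordinates to integer chunk indices.

    Coordinates exactly equal to the upper bound ``pv[d]`` are clamped into
    the last chunk ``pv[d] - 1`` so the grid covers the closed range.
    """
    Xn = np.asarray(Xn, dtype=float)
    pv = np.asarray(pv, dtype=int)
    # tolerate last-ulp overshoot of pv * (x - lo) / span at the range ends
    tol = 1e-9 * pv
    if np.any(Xn < -tol) or np.any(Xn > pv + tol):
        raise ContractError("normalised coordinates outside [0, PV] range")
    idx = np.floor(Xn).astype(np.int64)
    np.clip(idx, 0, pv - 1, out=idx)
    return idx


def chunkify_array(Xn, pn: int, cell_budget: int = DEFAULT_CELL_BUDGET) -> np.ndarray:
    """Count points per chunk into a dense ``(pn,) * N`` integer array."""
    Xn = _as_matrix(Xn)
    n_dim = Xn.shape[1]
    n_cells = pn**n_dim
    if n_cells > cell_budget:
        raise CellBudgetError(
            f"dense chunk array needs {n_cells} cells (PN={pn}, N={n_dim}), "
            f"exceeding the budget of {cell_budget}; use the graph-based ISBM"
        )
    idx = chunk_indices(Xn, (pn,) * n_dim)
    counts = np.zeros((pn,) * n_dim, dtype=np.int64)
    np.add.at(counts, tuple(idx.T), 1)
    return counts


def _neighbour_max(counts: np.ndarray) -> np.ndarray:
    """Max count among the 3**N - 1 neighbours of each cell (excluding self)."""
    footprint = np.ones((3,) * counts.ndim, dtype=bool)
    footprint[(1,) * counts.ndim] = False
    return ndimage.maximum_filter(
        counts, footprint=footprint, mode="constant", cval=0
    )


def find_centroids_array(counts: np.ndarray, threshold: int) -> list[tuple[int, ...]]:
    """Centroid candidates: chunks with count > threshold that strictly
    dominate every diagonal-inclusive neighbour.

    Returned sorted by descending count, ties by ascending lexicographic
    coordinate, which fixes the (deterministic) expansion order.
    """
    neigh = _neighbour_max(counts)
    mask = (counts > threshold) & (counts > neigh)
    coords = [tuple(int(c) for c in xy) for xy in np.argwhere(mask)]
    coords.sort(key=lambda c: (-counts[c], c))
    return coords


def _array_neighbours(coord: tuple[int, ...], shape: tuple[int, ...]):
    for delta in product((-1, 0, 1), repeat=len(coord)):
        if all(d == 0 for d in delta):
            continue
        nb = tuple(c + d for c, d in zip(coord, delta))
        if all(0 <= v < s for v, s in zip(nb, shape)):
            yield nb


def expand_array(counts: np.ndarray, centroids: list[tuple[int, ...]]) -> np.ndarray:
    """Grow one cluster per centroid by BFS over occupied chunks.

    A neighbouring chunk joins the frontier iff it is still unlabelled,
    occupied, and its count does not exceed the count of the chunk it is
    reached from (monotone descent from the mode).  A pending centroid
    candidate reached this way is merged into the expanding cluster and
    never seeds its own.  Chunks never reached keep the noise label 0.
    """
    labels = np.zeros_like(counts, dtype=np.int64)
    pending = set(centroids)
    next_label = 1
    for centroid in centroids:
        if centroid not in pending:
            continue  # merged into an earlier cluster
        pending.discard(centroid)
        label = next_label
        next_label += 1
        labels[centroid] = label
        queue = deque([centroid])
        while queue:
            cur = queue.popleft()
            cur_count = counts[cur]
            for nb in _array_neighbours(cur, counts.shape):
                if labels[nb] == 0 and 0 < counts[nb] <= cur_count:
                    labels[nb] = label
                    pending.discard(nb)
                    queue.append(nb)
    return labels


def dechunkify(chunk_labels: np.ndarray, Xn: np.ndarray) -> np.ndarray:
    """Assign every point the label of its (clamped-floor) chunk."""
    idx = chunk_indices(_as_matrix(Xn), chunk_labels.shape)
    return chunk_labels[tuple(idx.T)]


def sbm_fit(X, params: SBMParams, cell_budget: int = DEFAULT_CELL_BUDGET) -> ClusteringResult:
    """Run the full five-stage SBM pipeline on a raw point cloud.

    Deterministic: identical input always yields identical labels.
    Clusters are numbered from 1; noise is 0.
    """
    Xn = minmax_normalise(X, params.pn)
    counts = chunkify_array(Xn, params.pn, cell_budget=cell_budget)
    centroids = find_centroids_array(counts, params.threshold)
    chunk_labels = expand_array(counts, centroids)
    labels = dechunkify(chunk_labels, Xn)
    return ClusteringResult(
        labels=labels,
        noise_label=NOISE_LABEL_SBM,
        chunk_stats={
            "occupied_chunks": int(np.count_nonzero(counts)),
            "total_cells": int(counts.size),
            "centroids_found": len(centroids),
        },
    )
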