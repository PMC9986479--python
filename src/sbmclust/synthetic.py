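"""Synthetic point clouds with the structure spike-sorting feature spaces show.

Spike-sorting clustering problems are characterised by *imbalance* (neurons
fire at very different rates, so clusters have very different sizes) and
*overlap* (feature extraction rarely separates units cleanly).  The
generators here produce labelled Gaussian mixtures with exactly that
structure, so the clustering and metric modules can be exercised without
any recorded data.

The Unbalance-Overlapping (UO) benchmark is a fixed two-dimensional
mixture of 4,300 points in 6 isotropic Gaussian clusters whose sizes span
two orders of magnitude (50 to 1,250 points) and whose centres sit close
enough that neighbouring clusters overlap visibly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

#: UO cluster centres, in printed order.
UO_CENTERS: tuple[tuple[float, float], ...] = (
    (-2.0, 0.0),
    (-2.0, 3.0),
    (3.0, -2.0),
    (5.0, 6.0),
    (4.0, -1.0),
    (1.0, -2.0),
)

#: UO cluster sizes, aligned with :data:`UO_CENTERS` (total 4,300 points).
UO_SIZES: tuple[int, ...] = (500, 50, 1000, 1250, 250, 1250)

#: Default isotropic standard deviation of each UO cluster.  The centre
#: spacings (3 units and less between neighbours) then yield the
#: visible-but-overlapping structure the benchmark is named after.
UO_DEFAULT_SD = 1.0


@dataclass(frozen=True)
class ClusterSpec:
    """One Gaussian component: centre, point count, per-dimension SD."""

    center: tuple[float, ...]
    size: int
    sd: tuple[float, ...]

    def __post_init__(self):
        if self.size < 1:
            raise ParameterError(f"cluster size must be >= 1, got {self.size}")
        if len(self.sd) != len(self.center):
            raise ParameterError("sd length must equal center length")
        if any(s <= 0 for s in self.sd):
            raise ParameterError(f"sd must be positive in every dimension: {self.sd}")

    @classmethod
    def make(cls, center, size, sd) -> "ClusterSpec":
        """Build a spec, broadcasting a scalar ``sd`` over all dimensions."""
        center = tuple(float(c) for c in np.atleast_1d(center))
        sd = np.atleast_1d(np.asarray(sd, dtype=float))
        if sd.size == 1:
            sd = np.repeat(sd, len(center))
        return cls(center=center, size=int(size), sd=tuple(float(s) for s in sd))


@dataclass(frozen=True)
class LabeledCloud:
    """A generated point cloud with its block-ordered ground-truth labels."""

    points: np.ndarray  # (n, N) float
    labels: np.ndarray  # (n,) int, values 0..k-1

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def generate_mixture(specs: list[ClusterSpec], seed: int) -> LabeledCloud:
    """Sample a labelled Gaussian mixture, one block per spec in order.

    Cluster ``c`` contributes exactly ``specs[c].size`` draws from
    ``N(center_c, diag(sd_c**2))``; labels follow spec order and points are
    not shuffled.  A single seeded generator drives all sampling, so output
    is bit-identical for a fixed seed.
    """
    if not specs:
        raise ParameterError("at least one ClusterSpec is required")
    dims = {len(s.center) for s in specs}
    if len(dims) != 1:
        raise ParameterError(f"all specs must share dimensionality, got {dims}")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for c, spec in enumerate(specs):
        blocks.append(
            rng.normal(spec.center, spec.sd, size=(spec.size, len(spec.center)))
        )
        labels.append(np.full(spec.size, c, dtype=np.int64))
    return LabeledCloud(points=np.vstack(blocks), labels=np.concatenate(labels))


def uo_specs(sd: float = UO_DEFAULT_SD) -> list[ClusterSpec]:
    """The six UO cluster specs at the given isotropic SD."""
    if sd <= 0:
        raise ParameterError(f"sd must be positive, got {sd}")
    return [
        ClusterSpec.make(center, size, sd)
        for center, size in zip(UO_CENTERS, UO_SIZES)
    ]


def generate_uo(seed: int, sd: float = UO_DEFAULT_SD) -> LabeledCloud:
    """Generate the Unbalance-Overlapping dataset: 4,300 points, 6 clusters.

    Sizes (500, 50, 1000, 1250, 250, 1250) at centres (-2,0), (-2,3),
    (3,-2), (5,6), (4,-1), (1,-2); each cluster an isotropic Gaussian of
    standard deviation ``sd``.
    """
    return generate_mixture(uo_specs(sd), seed)


def generate_uo_scaled(
    total: int, seed: int, sd: float = UO_DEFAULT_SD
) -> LabeledCloud:
    """UO with cluster sizes rescaled to roughly ``total`` points.

    Each cluster size is multiplied by ``total / 4300`` and rounded; any
    rounding remainder is absorbed by the largest cluster.  Used by the
    runtime-scaling probe, which varies the sample size of UO.
    """
    if total < len(UO_SIZES):
        raise ParameterError(f"total must be >= {len(UO_SIZES)}, got {total}")
    factor = total / sum(UO_SIZES)
    sizes = [max(1, round(s * factor)) for s in UO_SIZES]
    sizes[int(np.argmax(UO_SIZES))] += total - sum(sizes)
    specs = [
        ClusterSpec.make(center, size, sd)
        for center, size in zip(UO_CENTERS, sizes)
    ]
    return generate_mixture(specs, seed)


def singleton_labeling(n: int) -> np.ndarray:
    """Labels 0..n-1: every point its own cluster (a perfect-score fixture
    for overclustering-tolerant metrics)."""
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    return np.arange(n, dtype=np.int64)


def write_labeled_csv(cloud: LabeledCloud, path) -> None:
    """Write one row per point: feature columns then a ``label`` column."""
    header = [f"f{d}" for d in range(cloud.n_features)] + ["label"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row, lab in zip(cloud.points, cloud.labels):
            writer.writerow([repr(float(v)) for v in row] + [int(lab)])
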