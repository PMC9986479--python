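"""Benchmark harness: run SBM/ISBM and reference algorithms, score, tabulate.

Mirrors the evaluation design used for grid-density spike-sorting
clustering: a roster of algorithms is fitted on a generated or
user-supplied feature space, every fit is scored with the external metric
suite (ARI, AMI, Purity, FMI, V-measure, SCS, reported x100), and the
chunk-count/space accounting and runtime scaling of the two pipeline
variants are tabulated separately.

Reference algorithms are called through scikit-learn (and through optional
third-party packages where installed); absence of an optional algorithm
degrades the roster with a recorded missing row, never the run.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import isbm, metrics, sbm, synthetic
from .exceptions import ParameterError

#: Algorithms that may legitimately be absent from the environment.
OPTIONAL_ALGORITHMS = frozenset({"hdbscan", "fcm", "isosplit"})


# ---------------------------------------------------------------------------
# roster


def _fit_sbm(X, params, seed):
    p = sbm.SBMParams(
        pn=int(params.get("pn", 25)),
        threshold=int(params.get("threshold", sbm.DEFAULT_THRESHOLD)),
    )
    return sbm.sbm_fit(X, p).labels, sbm.NOISE_LABEL_SBM


def _fit_isbm(X, params, seed):
    p = sbm.SBMParams(
        pn=int(params.get("pn", 25)),
        threshold=int(params.get("threshold", sbm.DEFAULT_THRESHOLD)),
    )
    pv = params.get("pv")
    return isbm.isbm_fit(X, p, pv=pv).labels, isbm.NOISE_LABEL_ISBM


def _fit_kmeans(X, params, seed):
    from sklearn.cluster import KMeans

    k = int(params["n_clusters"])
    model = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return model.fit_predict(X), None


def _fit_dbscan(X, params, seed):
    from sklearn.cluster import DBSCAN

    eps = params.get("eps")
    if eps is None:
        eps = elbow_eps(X)
    min_samples = int(params.get("min_samples", max(1, round(np.log(len(X))))))
    return DBSCAN(eps=float(eps), min_samples=min_samples).fit_predict(X), -1


def _fit_meanshift(X, params, seed):
    from sklearn.cluster import MeanShift, estimate_bandwidth

    bw = params.get("bandwidth")
    if bw is None:
        bw = estimate_bandwidth(X, quantile=0.2, random_state=seed)
    return MeanShift(bandwidth=float(bw)).fit_predict(X), None


def _fit_agglomerative(X, params, seed):
    from sklearn.cluster import AgglomerativeClustering

    k = int(params["n_clusters"])
    model = AgglomerativeClustering(n_clusters=k, linkage=params.get("linkage", "ward"))
    return model.fit_predict(X), None


def _fit_hdbscan(X, params, seed):
    import hdbscan  # optional dependency

    model = hdbscan.HDBSCAN(min_cluster_size=int(params.get("min_cluster_size", 5)))
    return model.fit_predict(X), -1


def _fit_fcm(X, params, seed):
    import skfuzzy  # optional dependency

    cntr, u, *_ = skfuzzy.cluster.cmeans(
        X.T, int(params["n_clusters"]), 2, error=1e-5, maxiter=300, seed=seed
    )
    return np.argmax(u, axis=0), None


ALGORITHMS = {
    "sbm": _fit_sbm,
    "isbm": _fit_isbm,
    "kmeans": _fit_kmeans,
    "dbscan": _fit_dbscan,
    "meanshift": _fit_meanshift,
    "agglomerative": _fit_agglomerative,
    "hdbscan": _fit_hdbscan,
    "fcm": _fit_fcm,
}


def elbow_eps(X, k: int = 4, quantile: float = 0.95) -> float:
    """DBSCAN eps heuristic: a high quantile of sorted k-NN distances."""
    from sklearn.neighbors import NearestNeighbors

    dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(X).kneighbors(X)
    d = np.sort(dist[:, -1])
    return float(d[int(quantile * (len(d) - 1))])


# ---------------------------------------------------------------------------
# configuration and report


@dataclass
class BenchmarkConfig:
    """Declarative description of one benchmark run.

    ``dataset`` is either ``{"generator": "uo", "sd": ..}``,
    ``{"generator": "mixture", "specs": [{center, size, sd}, ..]}`` or
    ``{"path": "file.csv", "label_column": "label"}``.  ``roster`` maps
    algorithm name -> parameter dict.
    """

    dataset: dict
    roster: dict[str, dict]
    seed: int = 0
    repetitions: int = 1
    pca_components: int | None = None
    exclude_noise: bool = False

    def __post_init__(self):
        if not self.roster:
            raise ParameterError("roster must not be empty")
        if self.repetitions < 1:
            raise ParameterError("repetitions must be >= 1")
        for name in self.roster:
            if name not in ALGORITHMS:
                raise ParameterError(
                    f"unknown algorithm {name!r}; known: {sorted(ALGORITHMS)}"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        return cls(
            dataset=d["dataset"],
            roster={r["name"]: r.get("params", {}) for r in d["roster"]}
            if isinstance(d["roster"], list)
            else d["roster"],
            seed=int(d.get("seed", 0)),
            repetitions=int(d.get("repetitions", 1)),
            pca_components=d.get("pca_components"),
            exclude_noise=bool(d.get("exclude_noise", False)),
        )


@dataclass
class BenchmarkReport:
    """Mean x100 metric table plus provenance; regenerable from ``config``."""

    scores: pd.DataFrame  # index: algorithm; columns: metrics (x100)
    missing: dict[str, str]  # algorithm -> reason it produced no row
    provenance: dict = field(default_factory=dict)


def _load_dataset(dataset: dict, seed: int):
    if "path" in dataset:
        df = pd.read_csv(dataset["path"])
        label_col = dataset.get("label_column", "label")
        if label_col in df.columns:
            y = df[label_col].to_numpy(dtype=np.int64)
            X = df.drop(columns=[label_col]).to_numpy(dtype=float)
        else:
            y = None
            X = df.to_numpy(dtype=float)
        return X, y
    gen = dataset.get("generator", "uo")
    if gen == "uo":
        cloud = synthetic.generate_uo(seed, sd=dataset.get("sd", synthetic.UO_DEFAULT_SD))
    elif gen == "mixture":
        specs = [
            synthetic.ClusterSpec.make(s["center"], s["size"], s["sd"])
            for s in dataset["specs"]
        ]
        cloud = synthetic.generate_mixture(specs, seed)
    else:
        raise ParameterError(f"unknown generator {gen!r}")
    return cloud.points, cloud.labels


def pca_reduce(X, n_components: int, seed: int = 0) -> np.ndarray:
    """PCA with a deterministic sign convention: each component's
    largest-magnitude loading is made positive."""
    pca = PCA(n_components=n_components, random_state=seed)
    Z = pca.fit_transform(X)
    for i, comp in enumerate(pca.components_):
        if comp[np.argmax(np.abs(comp))] < 0:
            Z[:, i] *= -1
    return Z


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Fit every roster algorithm over all repetitions and average scores.

    Each repetition reseeds the generator deterministically (base seed +
    repetition index).  A failed or unavailable fit is recorded in
    ``missing`` and the run continues.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    missing: dict[str, str] = {}
    for rep in range(config.repetitions):
        rep_seed = config.seed + rep
        X, y = _load_dataset(config.dataset, rep_seed)
        if config.pca_components is not None:
            X = pca_reduce(X, config.pca_components, seed=config.seed)
        if y is None:
            raise ParameterError("benchmark scoring requires ground-truth labels")
        for name, params in config.roster.items():
            if name in missing:
                continue
            try:
                labels, noise_label = ALGORITHMS[name](X, dict(params), rep_seed)
            except ImportError as exc:
                if name in OPTIONAL_ALGORITHMS:
                    missing[name] = f"optional algorithm unavailable: {exc}"
                    continue
                raise
            except Exception as exc:  # failed fit: record, keep running
                missing[name] = f"fit failed: {exc!r}"
                continue
            rep_scores = metrics.metric_suite(
                y, labels, noise_label=noise_label, exclude_noise=config.exclude_noise
            ).scaled
            vec = np.array([rep_scores[m] for m in metrics.SUITE_METRICS])
            sums[name] = sums.get(name, 0) + vec
            counts[name] = counts.get(name, 0) + 1
    rows = {
        name: sums[name] / counts[name] for name in config.roster if name in sums
    }
    scores = pd.DataFrame.from_dict(
        rows, orient="index", columns=list(metrics.SUITE_METRICS)
    )
    provenance = {
        "config": config,
        "numpy": np.__version__,
        "python": platform.python_version(),
    }
    return BenchmarkReport(scores=scores, missing=missing, provenance=provenance)


# ---------------------------------------------------------------------------
# space accounting and runtime scaling


def chunk_statistics(X, pn: int, dims: list[int], threshold: int | None = None) -> pd.DataFrame:
    """Chunk/node accounting per dimensionality.

    For each requested dimensionality d (obtained from ``X`` by PCA), the
    table reports the dense array's cell count ``pn**d``, the sparse graph's
    node count under a uniform partitioning vector, and the node count under
    the variance-adaptive partitioning vector.
    """
    X = np.asarray(X, dtype=float)
    rows = []
    for d in dims:
        if d > X.shape[1]:
            raise ParameterError(f"requested {d} dims but data has {X.shape[1]}")
        Xd = pca_reduce(X, d) if d < X.shape[1] else X
        uniform_pv = (pn,) * d
        g_uniform = isbm.chunkify_graph(isbm.normalise_with_pv(Xd, uniform_pv), uniform_pv)
        spec = isbm.compute_partition_vector(Xd, pn)
        g_adaptive = isbm.chunkify_graph(isbm.normalise_with_pv(Xd, spec.pv), spec.pv)
        rows.append(
            {
                "dims": d,
                "dense_cells": pn**d,
                "graph_nodes_uniform": len(g_uniform),
                "graph_nodes_adaptive": len(g_adaptive),
            }
        )
    return pd.DataFrame(rows)


def scaling_probe(
    sizes: list[int],
    seed: int = 0,
    pn: int = 25,
    threshold: int = sbm.DEFAULT_THRESHOLD,
    best_of: int = 3,
) -> pd.DataFrame:
    """Wall-clock runtime of sbm/isbm while varying the UO sample size.

    Times are best-of-``best_of`` on a monotonic clock; the table also
    reports, per consecutive size pair, the runtime ratio (a doubling of n
    under linear scaling gives a ratio near 2, quadratic near 4).
    Absolute seconds are hardware-dependent and never asserted in tests.
    """
    if list(sizes) != sorted(sizes):
        raise ParameterError("sizes must be increasing")
    params = sbm.SBMParams(pn=pn, threshold=threshold)
    rows = []
    for size in sizes:
        cloud = synthetic.generate_uo_scaled(size, seed)
        t_sbm = min(
            _timed(lambda: sbm.sbm_fit(cloud.points, params)) for _ in range(best_of)
        )
        t_isbm = min(
            _timed(lambda: isbm.isbm_fit(cloud.points, params)) for _ in range(best_of)
        )
        rows.append({"n": size, "sbm_s": t_sbm, "isbm_s": t_isbm})
    df = pd.DataFrame(rows)
    df["sbm_ratio"] = df["sbm_s"] / df["sbm_s"].shift(1)
    df["isbm_ratio"] = df["isbm_s"] / df["isbm_s"].shift(1)
    return df


def _timed(fn) -> float:
    t0 = time.perf_counter()
    fn()
    return time.perf_counter() - t0


def search_partitioning_number(
    X,
    true_labels,
    pn_values,
    threshold: int = sbm.DEFAULT_THRESHOLD,
    metric: str = "ARI",
) -> int:
    """Exploratory search of PN for ISBM, per the recommended practice of
    starting from the suggested value and scanning around it.

    Selects the PN maximising the requested metric against the supplied
    ground truth (ties resolved toward the smallest PN); this mirrors the
    per-dataset parametrisation used when benchmarking against labelled
    data.
    """
    from sklearn.metrics import adjusted_rand_score

    best_pn, best_score = None, -np.inf
    for pn in pn_values:
        res = isbm.isbm_fit(X, sbm.SBMParams(pn=int(pn), threshold=threshold))
        if metric == "ARI":
            score = adjusted_rand_score(true_labels, res.labels)
        elif metric == "SCS":
            score = metrics.spike_cluster_score(
                true_labels, res.labels, isbm.NOISE_LABEL_ISBM
            )
        else:
            raise ParameterError(f"unknown search metric {metric!r}")
        if score > best_score:
            best_pn, best_score = int(pn), score
    return best_pn
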