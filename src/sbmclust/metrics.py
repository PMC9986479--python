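"""External clustering validation: Spike Cluster Score, Purity, and adapters.

The Spike Cluster Score (SCS) is an external metric built for spike
sorting, where splitting one neuron's spikes across several predicted
clusters (overclustering) is recoverable by a later merge and should not
be punished, while mixing several neurons into one cluster
(underclustering) is close to unrecoverable and should be.

For each unique true label T_i, restrict the predictions to the points
whose truth is T_i and let P_j be the most frequent non-noise predicted
label in that restriction.  Then::

    Score(T_i) = count(P(T_i) = P_j) / count(P = P_j)

i.e. the fraction of P_j's *global* occurrences that fall inside T_i.  The
overall score is the unweighted mean of Score(T_i) over unique true
labels.  A predicted cluster entirely inside one true cluster scores
perfectly regardless of how finely it is split, so singleton labelling
scores 1; a predicted cluster straddling two true clusters is penalised in
both.  Noise-labelled predictions are excluded from P_j candidacy, which
makes the score invariant to removing noise-predicted points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

#: Metric names reported by :func:`metric_suite`, in report order.
SUITE_METRICS = ("ARI", "AMI", "Purity", "FMI", "VM", "SCS")


@dataclass
class MetricReport:
    """Scores of the full metric suite for one (truth, prediction) pair.

    ``raw`` holds each metric on its natural scale; ``scaled`` multiplies
    by 100 for display.  ``scs_breakdown`` maps each unique true label to
    its per-label score.
    """

    raw: dict[str, float]
    scs_breakdown: dict[int, float]

    @property
    def scaled(self) -> dict[str, float]:
        return {k: 100.0 * v for k, v in self.raw.items()}


def _check_pair(true_labels, pred_labels):
    t = np.asarray(true_labels).ravel()
    p = np.asarray(pred_labels).ravel()
    if t.size == 0 or t.size != p.size:
        raise ValueError(
            f"label vectors must be non-empty and equal length, got {t.size}, {p.size}"
        )
    return t, p


def scs_breakdown(
    true_labels, pred_labels, noise_label: int | None = None
) -> dict[int, float]:
    """Per-true-label Spike Cluster Scores.

    For ties in the highest within-subset count, the candidate maximising
    the score is chosen (the most charitable deterministic reading), with
    remaining ties broken by the smallest label value.  A true label whose
    subset contains only noise predictions scores 0, with a warning.
    """
    t, p = _check_pair(true_labels, pred_labels)
    global_counts: dict[int, int] = dict(zip(*np.unique(p, return_counts=True)))
    out: dict[int, float] = {}
    for ti in np.unique(t):
        subset = p[t == ti]
        labs, counts = np.unique(subset, return_counts=True)
        if noise_label is not None:
            keep = labs != noise_label
            labs, counts = labs[keep], counts[keep]
        if labs.size == 0:
            warnings.warn(
                f"true label {ti} is predicted entirely as noise; scoring it 0",
                stacklevel=2,
            )
            out[int(ti)] = 0.0
            continue
        top = counts.max()
        best = max(
            (int(l) for l, c in zip(labs, counts) if c == top),
            key=lambda l: (top / global_counts[l], -l),
        )
        out[int(ti)] = top / global_counts[best]
    return out


def spike_cluster_score(
    true_labels, pred_labels, noise_label: int | None = None
) -> float:
    """Overall SCS: unweighted mean of the per-true-label scores, in [0, 1]."""
    breakdown = scs_breakdown(true_labels, pred_labels, noise_label)
    return float(np.mean(list(breakdown.values())))


def scs_noise_invariance_check(
    true_labels, pred_labels, noise_label: int
) -> bool:
    """Self-test: SCS is unchanged by dropping noise-predicted positions."""
    t, p = _check_pair(true_labels, pred_labels)
    full = spike_cluster_score(t, p, noise_label)
    keep = p != noise_label
    if not keep.any():
        return True
    reduced = spike_cluster_score(t[keep], p[keep], noise_label)
    return bool(np.isclose(full, reduced, rtol=0, atol=1e-12))


def purity(true_labels, pred_labels) -> float:
    """Purity: sum over predicted clusters of their largest single-true-label
    overlap, divided by n.  In [0, 1]; singleton predictions score 1."""
    t, p = _check_pair(true_labels, pred_labels)
    cont = skmetrics.cluster.contingency_matrix(t, p)
    return float(cont.max(axis=0).sum() / t.size)


def metric_suite(
    true_labels,
    pred_labels,
    noise_label: int | None = None,
    exclude_noise: bool = False,
) -> MetricReport:
    """Score a prediction with ARI, AMI, Purity, FMI, V-measure, and SCS.

    When ``exclude_noise`` is set, positions predicted as ``noise_label``
    are dropped before every metric except SCS, which is invariant to such
    removal by construction and always sees the full vectors.
    """
    t, p = _check_pair(true_labels, pred_labels)
    breakdown = scs_breakdown(t, p, noise_label)
    scs = float(np.mean(list(breakdown.values())))

    ts, ps = t, p
    if exclude_noise and noise_label is not None:
        keep = p != noise_label
        if keep.any():
            ts, ps = t[keep], p[keep]
    raw = {
        "ARI": float(skmetrics.adjusted_rand_score(ts, ps)),
        "AMI": float(skmetrics.adjusted_mutual_info_score(ts, ps)),
        "Purity": purity(ts, ps),
        "FMI": float(skmetrics.fowlkes_mallows_score(ts, ps)),
        "VM": float(skmetrics.v_measure_score(ts, ps)),
        "SCS": scs,
    }
    return MetricReport(raw=raw, scs_breakdown=breakdown)
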