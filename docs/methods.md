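# Methods

## Model and assumptions

SBM/ISBM are mode-seeking grid methods: a cluster is the basin of a local
maximum of the chunk-count histogram, grown by breadth-first search along
non-increasing counts. The implicit assumption is that each unit
(neuron) contributes a unimodal, roughly Gaussian blob in feature space.
Two true clusters merge when their density modes fuse; one true cluster
splits when sampling noise creates several local maxima at fine grids.
The method never computes distances, so it is insensitive to cluster
imbalance in a way centroid methods are not, but it is sensitive to the
grid resolution *PN*.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `pn` | partitions/feature | required (suggestion available) | grid resolution; the highest-variance feature's partition count under ISBM |
| `threshold` | points/chunk | 5 | minimum count (exclusive) for centroid candidacy; guards against isolated noise points seeding clusters. No canonical default exists; 5 suppresses single-digit noise aggregations at the benchmark's densities while leaving the 50-point UO cluster (whose modal chunks hold tens of points at moderate PN) able to seed |
| `cell_budget` | cells | 5·10⁷ | dense-array refusal limit; the graph pipeline has no such limit |
| `cap` in `suggest_pn` | partitions | 50 | clamp on the suggested PN |

The suggestion `PN = round(n·max_d var_d / 10)` (variances on
[0,1]-normalised data, result clamped to [2, cap]) is a starting point for
an exploratory search, not an optimum; `search_partitioning_number`
implements that search against labelled data, mirroring the per-dataset
parametrisation used when benchmarking.

## Numerical and tie-break choices

* **Upper-boundary clamp** — a normalised coordinate exactly equal to
  `PV_d` floors into chunk `PV_d − 1`; a 1e-9-relative tolerance absorbs
  the last-ulp overshoot of `pv·(x−lo)/span` at the range maximum.
* **Centroid candidacy** is strict (`count > every neighbour`): an exact
  count plateau yields no candidate inside the plateau and its chunks are
  claimed only if some strictly-higher neighbour's expansion reaches
  them. The alternative (≥ with tie-breaking) would seed a candidate per
  plateau; strictness matches the "larger than its neighbours" rule
  literally and keeps candidacy local.
* **Processing order** — candidates are expanded in descending-count
  order, ties by ascending lexicographic coordinate. The order decides
  which cluster claims contested chunks and makes the pipeline fully
  deterministic.
* **Descent rule** — a chunk joins a frontier only if unlabelled,
  occupied, and its count ≤ the count of the chunk reaching it. A pending
  candidate absorbed this way is merged and never seeds its own cluster.
* **Partitioning-vector rounding** — `ceil`, floored at 2: a
  single-partition dimension carries no spatial information. Variances
  use the population formula (divide by n); after the ratio-to-max this
  is nearly immaterial but is fixed for reproducibility.
* **`normalise_with_pv` replicates `minmax_normalise`'s operation order**
  so a uniform PV reproduces the dense pipeline bit-exactly (tested).
* **Graph keys** are coordinate tuples internally, with an
  underscore-joined decimal string form exposed for serialisation; any
  stable bijective encoding is equivalent.
* **SCS ties** — if several predicted labels tie for the highest count
  inside a true cluster, the one maximising the score is chosen, then the
  smallest label: the most charitable deterministic reading.
* **SCS degenerate case** — a true cluster predicted entirely as noise is
  scored 0 with a warning. This is the one regime where the
  noise-invariance property cannot hold (removing the noise removes the
  cluster from the mean); the formula is undefined there and 0 is the
  conservative choice.
* **Noise exclusion in the metric suite** applies to ARI/AMI/Purity/
  FMI/V-measure (they treat the noise label as a genuine cluster and are
  contaminated by it) and never to SCS, which is invariant by
  construction.
* **PCA sign convention** in the benchmark harness: each component's
  largest-magnitude loading is forced positive, making reductions
  reproducible across runs.

## Synthetic data: what it emulates and what it does not

`generate_mixture` samples block-ordered isotropic (or per-dimension
diagonal) Gaussian mixtures with exact per-cluster counts — the imbalance
and overlap structure of spike-sorting feature spaces, with ground truth.
It does **not** simulate waveforms, multi-unit/noise clusters, electrode
drift, non-Gaussian feature distributions, or temporally correlated
sampling; passing tests on these mixtures shows the algorithm separates
unimodal Gaussian modes, not that it sorts real recordings.

The UO benchmark is reconstructed from its printed parameters: 4,300
points, 6 clusters, sizes (500, 50, 1000, 1250, 250, 1250), centres
(−2,0), (−2,3), (3,−2), (5,6), (4,−1), (1,−2). **The cluster standard
deviations are not printed anywhere**, and they matter: the default here
is isotropic sd = 1.0 per dimension, under which the three clusters at
(3,−2), (4,−1), (1,−2) — pairwise 1.4–2.2 units apart — fuse into one
density mode, capping every algorithm's achievable agreement with the
generating labels well below what the published benchmark reports. We
checked whether any isotropic sd reproduces the published cross-algorithm
score profile and none does (K-Means' published score implies sd ≈ 0.75,
DBSCAN's ≈ 0.4, ISBM's ≤ 0.35), so the original dataset presumably uses
unequal per-cluster covariances that are not recoverable from the printed
description. The sd is exposed as a parameter (`generate uo --sd`);
absolute UO scores from this reconstruction are therefore comparable
across algorithms run on it, but not directly against previously
published UO tables.

`generate_uo_scaled` rescales the six cluster sizes proportionally
(remainder absorbed by the largest cluster) for runtime-scaling
experiments.

## Problem sizes

Acceptance-level checks use the generated UO at its native 4,300 points
(30 seeds for score averaging), 50 random datasets up to n = 5,000 for the
space bound, 100 random datasets up to n = 2,000 for dense/sparse
equivalence, mixtures of n = 2,000 for parameter recovery, and UO scaled
4,300 → 34,400 for the runtime-scaling trend (5 seeds, best-of-3 timing,
ratios only — absolute seconds are hardware-dependent and never asserted).

## Known limitations

* Dense SBM refuses grids above the cell budget rather than attempting
  them; use ISBM for N ≳ 5 at moderate PN.
* ISBM's expansion cost grows with the 3^N neighbourhood, so very high
  dimensionality remains expensive even with the sparse graph; no
  approximate-neighbour acceleration is implemented.
* Count plateaus (exactly equal neighbouring counts) produce no centroid
  inside the plateau; at coarse grids this can leave whole regions noise.
* The exploratory PN search requires ground-truth labels; on unlabelled
  recordings the suggestion formula plus manual inspection is the
  intended workflow.
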