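# Benchmark the full roster on the generated Unbalance-Overlapping dataset.
#
# Run:  sbmclust bench run --config examples/bench_uo.yaml --out scratch/uo_bench
#
# Per-algorithm parameters below are library defaults / heuristics
# (unverified against any previously published per-dataset parameter
# tables); override them per dataset.  hdbscan and fcm are optional: when
# the packages are not installed the roster degrades with a recorded
# missing row.
dataset:
  generator: uo
  sd: 1.0
seed: 0
repetitions: 3
roster:
  - name: sbm
    params: {pn: 25, threshold: 5}
  - name: isbm
    params: {pn: 25, threshold: 5}
  - name: kmeans
    params: {n_clusters: 6}
  - name: dbscan
    params: {}          # eps from the k-NN elbow heuristic, min_samples ~ ln(n)
  - name: agglomerative
    params: {n_clusters: 6, linkage: ward}
  - name: hdbscan
    params: {min_cluster_size: 5}
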