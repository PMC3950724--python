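# ganet

Gene association network construction and analysis for large expression
compendia.

`ganet` scores every gene pair with a closed-form mutual-information (MI)
estimator based on the rank (Spearman) correlation transform,
`MI = -0.5 * ln(1 - rho_s^2)` nats, which captures any monotone dependence
and is orders of magnitude cheaper than kernel-density MI. Networks are
built by keeping the top fraction of pairs (default 10%) and pruning
likely-indirect edges with the data processing inequality (DPI) under a
tolerance parameter; a coarse network (tolerance 1.0, nothing removed) can
be tightened later without rescoring the matrix. Subnetworks are found with
Markov clustering (MCL), degree distributions are summarized with a
power-law fit, and each edge can be annotated with the experimental
conditions (chips) whose removal significantly reduces its MI — a
leave-one-chip-out z-test that links associations to the conditions under
which they operate.

A synthetic benchmark harness generates steady-state expression data from
known scale-free topologies (Hill-type transfer functions, propagated
biological noise, additive measurement noise) and evaluates inference
methods with confusion counts, ROC/AUROC, precision–recall and F-scores.

## Input format

Tab-delimited text (optionally gzipped): first row is a header whose first
cell is ignored and whose remaining cells are chip names; each following
row is a gene identifier and one numeric value per chip. Values are
assumed already normalized; missing values are rejected at load.

## CLI

```bash
# coarse network: MI scoring, top-10% threshold, DPI tolerance 1.0
ganet build --input expr.tsv --out run1 --keep-top 0.10 --dpi-tolerance 1.0

# coarse-to-fine refinement of an existing edge list
ganet refine --edges run1/network.tsv --mi-threshold 0.5281 \
             --dpi-tolerance 0.155 --out refined.tsv

# subnetwork discovery
ganet cluster --edges refined.tsv --inflation 2.0 --out clusters.tsv

# condition annotation (leave-one-chip-out z-test)
ganet conditions --edges refined.tsv --input expr.tsv \
                 --alpha 1e-4 --top-k 10 --out conditions.tsv

# synthetic data + method comparison
ganet simulate --n-genes 400 --n-samples 500 --seed 1 --out simdir
ganet benchmark --n-genes 400 --sample-sizes 200,400,600,800,1000 --seed 1

# full pipeline from a key-value config file
ganet run --config run.cfg
```

Exit codes: 0 success, 2 usage/config error, 3 data validation error,
4 numerical failure. All tabular outputs are tab-delimited with
`#`-prefixed provenance headers (version, config hash, seed — no
timestamps, so reruns are byte-identical) and import directly into
Cytoscape.

## Library

Every CLI stage is a plain function: `read_expression`, `pairwise_mi`,
`select_threshold`, `apply_dpi`, `build_network` / `refine`,
`mcl_cluster`, `significant_conditions`, `generate_topology` /
`simulate_expression` / `evaluate_scores` / `benchmark_methods`. See
docstrings in `src/ganet/`.

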