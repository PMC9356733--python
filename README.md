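# dynrecon

Dynamic brain-network reconfiguration analysis as a tested, reusable
pipeline:

1. **Synthetic cohorts** (`dynrecon.synthetic`) — multi-site, two-group
   cohorts of ROI time series with *planted* piecewise-stationary community
   dynamics (group differences enter through per-network "detachment"
   probabilities; sites add affine mean/scale perturbations), so every
   downstream stage has ground truth.
2. **Dynamic networks** (`dynrecon.network`) — sliding-window Pearson
   connectivity (default: length 20, 50 % overlap), negative edges zeroed,
   one symmetric non-negative layer per window.
3. **Multilayer community detection** (`dynrecon.community`) — generalized
   Louvain maximization of the multilayer modularity
   `Q = (1/2mu) * sum[(A_ijl - gamma*V_ijl) delta_lr + delta_ij omega_jlr] delta(g_il, g_jr)`
   with a per-layer Newman–Girvan null model and ordinal interlayer
   coupling (defaults gamma = 1, omega = 0.4; 100 stochastic runs averaged
   into a module-allegiance matrix). The optimizer adds split-capable
   refinement and a budgeted Kernighan–Lin pass on top of greedy local
   moves; on small instances it reaches the exhaustively enumerated optimum
   (see `tests/test_acceptance.py`).
4. **Reconfiguration metrics** (`dynrecon.metrics`) — node/network
   recruitment, node integration, and pairwise network integration from the
   allegiance matrix: 9 recruitment + 36 integration coefficients for a
   9-network partition.
5. **Harmonization** (`dynrecon.harmonize`) — parametric empirical-Bayes
   batch adjustment (ComBat) of the metric table across sites, preserving
   the diagnosis covariate (optionally age).
6. **Group inference** (`dynrecon.inference`) — pooled-variance t-tests
   (Welch optional) over the 45 network-level coefficients with joint
   Benjamini–Hochberg FDR (q < 0.05), uncorrected ROI-level follow-up
   (p < 0.001) inside significant networks, age-stratified analysis
   ([7,12), [12,18), [18,25]), and an independent-cohort replication run.
7. **Pipeline/IO** (`dynrecon.io`, `dynrecon.cli`) — plain-CSV/JSON file
   formats, YAML run configuration, checksum-based resume, and a manifest
   for bit-reproducible runs.

A bundled 268-node partition fixture (49 cerebellar nodes excluded, nine
cerebral networks over the remaining 219) drives the default atlas-scale
layout; small 9-network demo partitions are used for simulation studies.

## CLI

```bash
dynrecon simulate --config sim.yaml --out cohort/ --seed 7
dynrecon run-all --cohort cohort/ --config run.yaml --out results/
dynrecon replicate --discovery results/results.csv \
    --metrics results_b/metrics_harmonized.csv --meta cohort_b/meta.csv \
    --out replication.csv
```

Stage-wise subcommands `construct`, `detect`, `metrics`, `harmonize`,
`compare` operate on single files; `--help` on any subcommand lists the
options. Exit codes: 0 success, 2 input error, 3 computation failure.

A cohort directory holds `timeseries/<subject>.csv` (T rows x K node
columns), `meta.csv` (subject_id, group, site, age), `partition.csv`
(node_id, network, excluded) and optionally `ground_truth.json`. Run
outputs are tidy CSV tables (`metrics_raw.csv`, `metrics_harmonized.csv`,
`results.csv`, `roi_results.csv`, per-age-bin tables) plus
`manifest.json` with config digest and output checksums.

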