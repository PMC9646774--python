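# cytomc

Mass-cytometry B-cell phenotyping pipeline: spillover compensation and
control-anchored batch normalization, PhenoGraph-style consensus graph
clustering, gap-statistic metaclustering, Shannon-entropy heterogeneity
statistics, light-chain clonality calls with tumor typing, and exact
probabilistic (hypergeometric) cluster co-occurrence networks — plus a
synthetic cohort generator that plants known population structure so the
whole pipeline can be exercised and validated without any external data.

## Modules

| module | what it does |
|---|---|
| `cytomc.core` | `CellTable` (cells × markers + annotations), `MarkerPanel` |
| `cytomc.synthetic` | multi-sample, multi-batch cohorts with planted clones, batch gains, spillover, pooled-control aliquots |
| `cytomc.preprocess` | NNLS spillover compensation, arcsinh transform (`asinh(0.2·x)`), control-median batch normalization, combined KL light-chain channel |
| `cytomc.clustering` | exact kNN → Jaccard-weighted graph → Louvain, repeated R times; consensus run selected by mean pairwise ARI (NMI tie-break); per-sample rare-cluster pruning |
| `cytomc.metacluster` | hierarchical (Ward) metaclustering of cluster median profiles, gap-statistic model selection, Kruskal–Wallis marker ranking for panel reduction |
| `cytomc.entropy` | per-cell inter-sample (K-NN mixing) entropy and per-sample intratumoral entropy (natural log) |
| `cytomc.clonality` | kappa:lambda clonality calls (polytypic within [0.3, 7]), Ab-cluster flagging, tumor typing (A / B / NOS / rLN-like, most-abundant and majority-50 rules) |
| `cytomc.cooccurrence` | presence matrices, exact hypergeometric pair co-occurrence, 2×2 exclusivity chi-square, Ward-on-JSD sample clustering, signed network export |
| `cytomc.pipeline`, `cytomc.cli` | file-based stage orchestration, YAML config, structured logging |

## CLI

```sh
# generate a planted synthetic cohort (CSV per sample + JSON manifest)
cytomc simulate --n-a 6 --n-b 6 --n-divergent 4 --cells 400 --out cohort/

# full pipeline from a YAML config (or the built-in demo cohort)
cytomc run --config config.yaml --out work/ --seed 7

# stages are individually re-runnable against one working directory
cytomc preprocess --workdir work/ --input-dir cohort/
cytomc cluster --workdir work/
cytomc metacluster --workdir work/
cytomc entropy --workdir work/
cytomc type --workdir work/
cytomc cooccur --workdir work/
cytomc report --workdir work/
```

Minimal `config.yaml`:

```yaml
seed: 7
simulate: {n_a: 6, n_b: 6, n_divergent: 4, cells_per_sample: 400}
k_neighbors: 20
runs: 5
```

Outputs land under the working directory: normalized cells and batch
factors, per-cell labels with consensus ARI/NMI matrices, metacluster map
and gap curve, clonality and typing tables, entropy CSVs, co-occurrence
report with a GraphML/TSV network, and a deterministic `report.json`.

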