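# trinet

Integrative mRNA/lncRNA/miRNA network inference from expression profiles,
and detection of cross-regulation **triplets** — 3-cliques of the network
containing exactly one protein-coding mRNA, one long noncoding RNA and one
microRNA.

The package is aimed at computational biologists working with matched
multi-omics expression cohorts (e.g. tumor RPKM profiles of coding genes,
lncRNAs and miRNAs over the same patients) who want a genome-wide,
correlation-symmetric map of which RNAs co-regulate which, and the
disease-relevant mRNA–lncRNA–miRNA units within it.

## Method

For each RNA *g*, its log expression across samples is the response
**y** and every other RNA is a candidate predictor in

```
argmin_β ‖y − Xβ‖₂² + λ₀‖β‖₀ ,    p ≫ n,
```

an l0-penalized least-squares problem solved approximately by **streamwise
VIF regression**: candidates are visited in a seeded random order; each
candidate's marginal t-statistic against the current residual is deflated
by √ρ, where ρ is the fraction of the candidate's variance left after
projection onto the already-selected predictors, estimated cheaply on a
small presample of rows; the corrected statistic enters an
**alpha-investing** test whose wealth budget controls false selections over
the stream (the operational role of λ₀). The selected support is refit by
OLS and the model is retained only when its **adjusted R²** exceeds 0.8.
Each retained (target, regulator) relation becomes an undirected edge —
the regressions cannot orient causality — and relations found in both
directions merge into one edge. Heterogeneous triangles of the resulting
typed graph are the triplets; optionally they are screened so that the
mRNA member belongs to a supplied pathway gene set (GMT format, e.g. the
KEGG endometrial-cancer pathway hsa05213).

A synthetic-data module generates RPKM-like cohorts with *planted*
triplets (three genes sharing a latent factor) and independent background
genes, so the whole pipeline is testable at desk scale with known ground
truth.

## Worked example

```
$ cat example.yaml
seed: 11
simulate:
  n_samples: 150
  n_mrna: 10
  n_lncrna: 10
  n_mirna: 5
  n_planted_triplets: 2
  latent_loading: 1.0
  noise_sd: 0.1
  zero_fraction: 0.02
network:
  cutoff: 0.8

$ trinet run-all --config example.yaml --out-dir demo
{
  "cutoff": 0.8,
  ...
  "network": {
    "max_degree": 2,
    "mean_degree": 2.0,
    "n_edges": 6,
    "n_vertices": 6,
    "vertices_per_type": {"lncRNA": 2, "mRNA": 2, "miRNA": 2}
  },
  "recovery": {"precision": 1.0, "recall": 1.0, "f1": 1.0},
  "retained_models": 6,
  "task_count": 25,
  "predictors_per_task": 24,
  "triplets": {"n_triplets": 2, "distinct_mrna": 2,
               "distinct_lncrna": 2, "distinct_mirna": 2}
}

$ head -3 demo/triplets.tsv
mrna    lncrna  mirna
GENE0000        LINC0000        hsa-mir-001
GENE0001        LINC0001        hsa-mir-002
```

25 genes give 25 regression tasks of 24 predictors each. Exactly the six
models whose targets are planted-triplet members surpass the adjusted-R²
cutoff, producing the six pairwise edges of the two planted triangles;
triangle enumeration returns both planted triplets and nothing else
(`recovery.recall = recovery.precision = 1.0`). Each artifact
(`combined.tsv`, `edges.tsv`, `triplets.tsv`, `report.json`) is
byte-reproducible from the same config and seed.

The same stages are available individually (`trinet simulate`,
`preprocess`, `build-network [--enumerate-only]`, `find-triplets`,
`screen`, `report`) and as library functions
(`trinet.StreamwiseVifRegressor`, `trinet.build_integrative_network`,
`trinet.find_heterogeneous_triangles`, ...). The regressor follows the
scikit-learn estimator protocol (`fit`/`predict`/`get_params`), so it
composes with sklearn model-selection tooling.

## Documentation

See `docs/methods.md` for the model, its assumptions, every tunable
parameter with defaults, what the synthetic generator does and does not
emulate, and known limitations.
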