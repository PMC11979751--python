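# statedecon

Cell-state analysis toolkit for transcriptomics: derive cell-state
trajectories from single-cell data via a within-cell binary gene-pair
relative-expression encoding, project bulk datasets into the same space,
select state markers with a cosine specificity distance, estimate cell-state
proportions in bulk mixtures by Nu-SVR deconvolution, impute state-specific
expression with positive Lasso regression, and cluster drug-perturbation
signatures on a hamming-distance neighbor graph.

A synthetic-data module generates ground-truthed inputs (multi-state
single-cell profiles with markers and batch effects, known-proportion bulk
mixtures, mechanism-classed drug signatures), so every stage is verifiable
without external downloads.

## Modules

| module | purpose |
|---|---|
| `statedecon.syndata` | ground-truthed synthetic single-cell/bulk/drug data |
| `statedecon.pair_encoding` | gene-pair binary encoding, bulk-concordance pair filter |
| `statedecon.trajectory` | hierarchical clustering, PCA trajectory, projection, DE, PC–gene correlation |
| `statedecon.markers` | detection fractions, specificity distance, k-means marker selection, discordance scoring |
| `statedecon.deconvolution` | signature building, Nu-SVR proportion estimation, positive-Lasso imputation |
| `statedecon.drugs` | signed signature matrix, hamming kNN graph, Leiden clustering, UMAP, susceptibility summaries |
| `statedecon.enrichment` | Fisher-exact gene-set enrichment with BH correction |
| `statedecon.io` / `statedecon.cli` / `statedecon.pipeline` | plain-text readers/writers, CLI, end-to-end orchestration |

## CLI

Every stage is a subcommand of `statedecon`; run `statedecon --help` for the
full list (`simulate`, `encode`, `trajectory`, `project`, `de`, `pc-corr`,
`crosstab`, `markers`, `discordance`, `signature`, `deconvolve`, `impute`,
`drug-graph`, `drug-overlap`, `drug-rank`, `target-summary`, `enrich`, `run`).

A full synthetic end-to-end run:

```bash
statedecon run --seed 0 --outdir out/
```

writes every stage artifact (expression matrices, pair list, state labels,
trajectory coordinates, DE table, markers, signature, proportions, imputed
expression, drug clusters and overlap tables, enrichment results) plus the
resolved configuration to `out/`. Individual stages operate on tab-delimited
text files, e.g.

```bash
statedecon simulate --n-genes 500 --seed 0 --outdir data/
statedecon encode --sc data/single_cell.tsv --bulk data/bulk.tsv \
    --n-top 400 --out data/pairs.tsv
statedecon trajectory --matrix data/single_cell.tsv --pairs data/pairs.tsv \
    --n-clusters 4 --out-prefix data/traj
statedecon markers --matrix data/single_cell.tsv --labels data/traj.states.tsv \
    --out data/markers.tsv
statedecon signature --matrix data/single_cell.tsv --labels data/traj.states.tsv \
    --markers data/markers.tsv --out data/signature.tsv
statedecon deconvolve --bulk data/bulk.tsv --signature data/signature.tsv \
    --out data/proportions.tsv
```

## Notes

- Expression inputs are genes-by-observations tab-delimited text in
  log2(TPM+1) (use `--space TPM` / `statedecon` transforms for linear data);
  an `--orientation observations_rows` flag transposes on load.
- All randomized stages take explicit seeds; identical seeds give identical
  outputs.
- Binary relative-expression concordance is computed in bounded-memory chunks
  and is bit-identical to the dense computation.
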