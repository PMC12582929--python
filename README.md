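# phaseomics

Differential abundance and cross-phase proteome prediction for two-strain
(wild type vs mutant) multi-omics growth-phase designs.

The package implements a complete, testable pipeline:

1. **I/O + normalisation** (`phaseomics.io`): wide TSV/CSV abundance
   matrices with sample metadata, MaxQuant `proteinGroups.txt` parsing
   (reverse/contaminant filtering, LFQ 0 → missing), internal-standard and
   wet-weight per-sample normalisation.
2. **Synthetic data** (`phaseomics.simulate`): seeded generator of
   two-strain, multi-phase metabolomics + proteomics datasets with planted
   log2 fold changes, pathway structure, detection censoring, and proteins
   generated as noisy linear functions of pathway-linked metabolites.
3. **Differential abundance** (`phaseomics.differential`): presence/absence
   screening, log2 fold changes, pooled-variance Student t-tests on log2
   values, Storey q-values, and the significance gate
   `p < 0.05 AND |log2FC| >= 0.58`.
4. **PCA** (`phaseomics.pca`): SVD-based PCA with deterministic sign
   convention, per-modality scaling, and pathway-annotated biplot tables.
5. **Regression benchmark** (`phaseomics.benchmark`): PLS / Ridge / Lasso /
   Random Forest / gradient-boosted trees under leave-one-out
   cross-validation with fold-local scaling and inner grid search; models
   ranked by MSE.
6. **Graph attention network** (`phaseomics.gat`): metabolite–protein graph
   from shared pathway labels; a two-layer, four-head GAT (128 hidden
   channels, ELU, batch norm, dropout 0.3) written in pure NumPy with
   hand-derived backprop, trained full-batch with Adam + step LR decay.
7. **Concordance reporting** (`phaseomics.report`, `phaseomics.pipeline`):
   predicted vs observed fold changes, Pearson concordance, directional
   agreement tables, cross-phase Venn/heatmap summaries, and a fully
   deterministic end-to-end pipeline with a JSON manifest.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence against brute-force reference implementations, GAT gradient /
equivariance checks, parameter recovery on synthetic data, bit-level
pipeline determinism).

## CLI

```sh
phaseomics simulate --seed 1 --out data/                 # synthetic dataset
phaseomics diffabund --matrix data/metabolomics_OD0.6.tsv \
    --meta data/samples.tsv --out diff.tsv
phaseomics pca --matrix data/metabolomics_OD0.6.tsv --meta data/samples.tsv \
    --out scores.tsv
phaseomics benchmark --metab-t0 ... --metab-t1 ... --prot-t0 ... \
    --prot-t1 ... --meta data/samples.tsv --out ranking.tsv
phaseomics gnn --pathways data/pathways.tsv ... --out gat_preds.tsv
phaseomics run --config config.yaml --out results/       # full pipeline
```

`phaseomics run` executes simulate → normalise → differential (per phase) →
PCA → benchmark → GAT → concordance and writes `manifest.json`; reruns under
the same seed are bit-identical.

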