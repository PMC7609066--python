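# scvasc

Rule-based single-cell and spatial transcriptomics analysis of brain
endothelial populations in a conditional-knockout (wt vs ko) mouse setting,
exercisable end to end on synthetic data generated in-repo.

The pipeline covers:

- **QC and normalization** — cells filtered when their detected-gene count
  falls outside mean ± 2 SD within their genotype group or their
  mitochondrial count fraction exceeds 5%; log-normalization to a scale
  factor of 10,000; per-gene regression on total molecule counts (nUMI);
  variance-stabilized variable-gene selection.
- **Clustering and resolution selection** — 30-PC PCA, shared-nearest-neighbor
  graph, modularity (Leiden) clustering scanned over a resolution grid
  (0.01–1 by default); a clustering tree with in-proportion edges selects the
  highest resolution inside a stable, not over-clustered region.
- **Markers and annotation** — one-vs-rest Wilcoxon rank-sum markers per
  genotype combined by the Tippett minimum-p method; clusters annotated by a
  cell type when ≥ 50% of its key genes pass (avg logFC > 0, combined
  p < 0.05); unique markers (avg logFC > 0.25, padj < 0.05) and unique
  ko-vs-wt DEGs (|logFC| > 0.2, padj < 0.05).
- **Population statistics** — ko/wt cell-count fold change per cluster or
  trajectory branch with flagging above the 95% t-CI upper limit; marker
  positivity by the > 0 and > Q1 rules; double-positive counts.
- **Gene-set over-representation** — hypergeometric tail p with BH q, fold
  enrichment odds, and the p < 0.05 / q / odds ≥ 4 / overlap > 2 filters;
  per-cluster disease-set overlap with two-sided Fisher tests.
- **Spatial spots** — conjunctive co-expression classification of spots
  (EC / lesion / tip / proliferating, thresholds 0.5 and 1 on log-normalized
  values) and a merged-sample Fisher exact comparison of proliferation
  proportions.
- **Synthetic data** — negative-binomial count simulator with planted
  clusters, marker genes, ko expansion, DE effects, mitochondrial fractions,
  zero-inflated positivity profiles, and spot mixtures with lesion /
  proliferation structure; every downstream stage is testable against ground
  truth without downloads.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact-enumeration
oracles for every statistical primitive, rule truth tables, parameter
recovery on planted synthetic data, and null controls.

## CLI

```sh
scvasc simulate --config sim.yaml --seed 0 --outdir data/
scvasc qc --matrix data/matrix.mtx --barcodes data/barcodes.tsv \
          --features data/features.tsv --cell-meta data/cell_meta.tsv \
          --out qc.tsv
scvasc cluster ... --resolutions 0.01,0.1,...,1.0 --out clusters.tsv
scvasc expand --counts cluster_counts.tsv --out expansion.tsv
scvasc enrich --query degs.txt --gmt hallmark.gmt --universe genes.txt --out enr.tsv
scvasc spots --spots spots.tsv --out flags.tsv --fisher-out fisher.json
scvasc run-all --config pipeline.yaml --seed 0 --outdir out/
```

`run-all` executes every configured stage from a single YAML file (see
`scvasc.pipeline.DEFAULT_CONFIG` for all keys and their defaults, which
reproduce the published settings) and writes a manifest with output hashes
for reproducibility.

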