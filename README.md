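# coexpact

A toolkit for small-panel RT-qPCR co-expression studies. It covers the full
analysis path from raw quantification cycles to disease-activity
classification:

- **`synthetic_data`** — synthetic cohort generation: Cq tables with a
  two-block gene correlation structure (positive within blocks, a
  per-condition between-block correlation that is strongly negative in one
  condition), candidate reference genes of controlled stability, clinical
  covariates with per-condition distributions, and random miRNA target maps.
- **`qpcr_quant`** — reference-gene stability (pairwise-variation M,
  intra/intergroup variance decomposition, SD/CV + index correlation),
  aggregate reference-pair selection, and `2^-ddCq` relative quantification.
- **`group_stats`** — Mann–Whitney (tie + continuity corrections by
  default, exact option), Pearson chi-square without continuity correction,
  KS normality screening, per-gene differential expression.
- **`coexpression`** — pairwise Pearson/Spearman correlation, network
  construction at conjunctive (r, p) thresholds, topology metrics
  (finite-pairs convention), gained/lost edges and multi-network overlap.
- **`clustering`** — complete-linkage hierarchical clustering on `1 - r`
  distance with a deterministic tie rule, cut-height module extraction,
  sample-separation summary, Newick export.
- **`activity_score`** — the regression-residual scoring system: OLS lines
  fit on a reference group, per-patient relative-error M-values, Youden
  thresholds, summed score cards, rank-probability ROC/AUC.
- **`tlr_closeness`** — the three-metric gene-set closeness score
  (adjacent probe genes, shared neighbors with the merged probe node,
  probes in the same cut-height cluster; one point per gene).
- **`mirna_network`** — miRNA target-map filtering (multi-target rule),
  family pooling, ranking, degree-filtered bipartite networks, and a
  simple fold-change stand-in for count tables.
- **`pipeline` / `cli`** — end-to-end orchestration with checksummed run
  manifests.

Packaged plain-text fixtures (a 27-patient clinical table, closeness
component counts, and enumerated cluster memberships) make the scoring and
statistics reproducible without any external data.

## CLI

```sh
coexpact simulate --seed 1 --cq-out cq.tsv --samples-out samples.csv
coexpact quantify --cq cq.tsv --samples samples.csv --refs auto --calibrator HC
coexpact network --expr expression.tsv --samples samples.csv --group treated-inactive
coexpact cluster --expr expression.tsv --samples samples.csv --group treated-inactive --cut-height 1.0
coexpact run --seed 1 --outdir run1          # full pipeline
coexpact report --manifest run1/manifest.json
```

Exit codes: 0 success, 2 config error, 3 data error, 4 stage failure.

## Notes

- Gene symbols in the default panel use ASCII names (`IkBa` for IκBα).
- Correlation analyses consume relative-expression values by default; a
  `correlation_scale: log2` switch correlates on the −dCq (log) scale
  instead, which is Spearman-equivalent and more robust for Pearson.
- The amplification efficiency is fixed at 2 (no efficiency correction).
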