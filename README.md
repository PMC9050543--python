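# nigra

Analysis toolkit for case/control midbrain single-nuclei studies, with
synthetic-data generators that plant known ground truth for every
downstream statistic. The package covers:

- **`nigra.simulate`** — generators for multi-sample UMI count matrices
  (planted cell types, batch effects, a case-exclusive rare cluster,
  doublets), branched activation trajectories with true pseudotime,
  multi-channel fluorescence images with exact per-object truth, and
  gene-level association statistics with planted set enrichments.
- **`nigra.qc`** — the barcode/gene filter cascade (UMI, detected genes,
  mito/ribo fractions, doublet score; gene detection and flag filters)
  with per-stage attrition reports, plus a self-contained doublet scorer.
- **`nigra.composition`** — 2D kernel density contrast on the embedding
  (log2 case/control ratio), per-sample proportion t-tests, beta
  regression of proportions on clinical covariates, pseudobulk Pearson
  similarity with average-linkage dendrogram, and one-vs-rest ROC marker
  scoring with the FDR/pct/logFC filter.
- **`nigra.trajectory`** — principal-graph pseudotime (k-means + MST
  surrogate) with supervised maximin rooting, pseudotime density
  contrast, Moran's I trajectory genes on a kNN graph, quasi-Poisson
  differential expression with size-factor offsets, and the
  DE × trajectory intersection.
- **`nigra.morphometry`** — bright/dark-object segmentation, per-region
  area fractions, skeleton branching (junction pixels, merged branch
  points and endpoints), per-individual summaries and unpaired t-tests.
- **`nigra.risk`** — competitive gene-set regression of association
  z-scores on marker-set membership, marker-set construction from score
  tables, and top-contributor ranking.
- **`nigra.annotation_cv`** — loess mean-variance normalization and
  stratified cross-validated label verification (truncated SVD + random
  forest) aggregated into a confusion matrix.

## CLI

Everything is reachable through the `nigra` entry point:

```sh
# synthetic data (config files are JSON overrides of the defaults)
nigra simulate counts     --config cfg.json --out sim/ --seed 1
nigra simulate trajectory --out traj/ --seed 1
nigra simulate images     --out imgs/ --seed 1
nigra simulate genestats  --out gs/   --seed 1

# QC cascade on an MTX triplet directory
nigra qc run --matrix sim/ --thresholds thr.json --out qc/

# composition analyses
nigra composition density|proportions|betareg|pseudobulk|markers \
    --matrix qc/ --out comp/

# trajectory analyses
nigra trajectory learn-root --matrix traj/ --activated-type activated_a \
    --n-centroids 12 --out tr/
nigra trajectory contrast --matrix traj/ --pseudotime tr/pseudotime.tsv --out tr/
nigra trajectory genes --matrix traj/ --out tr/
nigra trajectory de    --matrix traj/ --out tr/
nigra trajectory intersect --de tr/de.tsv --moran tr/morans_i.tsv \
    --direction up --out tr/intersection.txt

# morphometry
nigra morphometry segment  --image imgs/IBA1.tif --out seg/
nigra morphometry skeleton --mask seg/labels.tif --out skeleton.csv
nigra morphometry summarize --records objects.csv --individuals map.csv \
    --out summary.csv
nigra morphometry compare --summaries summary.csv --metric mean_area_px \
    --out compare.json

# risk enrichment
nigra risk test --genestats gs/gene_stats.tsv --out risk.tsv

# annotation cross-validation
nigra annotation-cv --matrix sim/ --out cv/
```

Count matrices are CellRanger-style triplets (`matrix.mtx`,
`features.tsv`, `barcodes.tsv`) plus `metadata.tsv` and, for synthetic
data, `truth.json` with the planted ground truth. Images are 16-bit
single-channel TIFFs with pixel-aligned label masks.

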