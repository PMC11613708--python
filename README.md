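# epichaos

Cluster-level cell-to-cell epigenetic heterogeneity scores for binarized
single-cell epigenomics matrices (scATAC-seq, scDNA-methylation,
scChIP-seq), with region-set analyses, a permutation-based differential
heterogeneity test, companion metrics (transcriptional noise, methylation
variability), and a full synthetic-data suite for validation.

## How scoring works

For each group of cells (cluster, cell type, condition, …):

1. every unordered cell pair gets a **chance-centered Jaccard
   similarity** `J − E`, where `J = a/(s1+s2−a)` and
   `E = p1·p2/(p1+p2−p1·p2)` is the expectation under independence given
   the two cells' 1-densities;
2. the **raw score** is the mean over all pairs;
3. raw scores are **adjusted** by regressing them (OLS, across all
   observations of the run) on the mean per-cell detected-feature count
   and keeping the residuals — removing residual sparsity effects;
4. adjusted scores are min-max scaled to [0, 1] and inverted, so **1 is
   the most heterogeneous group of the run**.

By default each group with ≥ 100 cells is scored on five random
100-cell subsamples. A per-chromosome variant (`--per-chromosome`)
adjusts within each chromosome and averages the residuals, making the
score robust to whole-chromosome copy-number alterations. Scores are
relative to a run; raw and adjusted columns are always emitted.

## CLI

```sh
# generate a synthetic controlled-heterogeneity series, then score it
epichaos simulate controlled --seed 1 --out sim/
epichaos score --matrix sim/ --groups sim/grouping.tsv --no-subsample \
    --seed 1 --out scores.tsv

# score a real matrix (MTX triplet: matrix.mtx + features.bed + barcodes.tsv)
epichaos score --matrix data/ --groups clusters.tsv --seed 7 --out scores.tsv

# region-set heterogeneity (one BED per set, filename = set name)
epichaos regions --matrix data/ --regions tfbs_beds/ --groups clusters.tsv \
    --out region_scores.tsv

# differential heterogeneity between two groups (1000 permutations)
epichaos diff --matrix data/ --groups clusters.tsv --group-a HSC \
    --group-b Mono --regions tfbs_beds/ --n-perm 1000 --seed 3 --out diff.tsv

# companion metrics
epichaos metrics cv --expr expression.tsv --out cv.tsv
epichaos metrics methylation --meth meth.tsv --regions tfbs_beds/ --out mv.tsv
```

Other generators: `epichaos simulate {perturb|sparsity|mixture|depth|cna|noise}`.
Every generator and scoring run is deterministic given `--seed`; outputs
are TSV with a sibling `.meta.json` carrying the full configuration and
a config hash. Coordinates are 0-based half-open (BED convention)
throughout.

## Python API

```python
import epichaos as ec
from epichaos import synthetic as syn

series = syn.gen_controlled_series(seed=1)
matrix, grouping = syn.combine_series(series)
scores = ec.compute_epichaos(matrix, grouping, subsample=False)
```

Key entry points: `compute_epichaos`, `per_chromosome_scores`,
`score_region_sets`, `differential_heterogeneity`,
`transcriptional_noise_cv`, `methylation_region_variability`, and the
`epichaos.synthetic` generators.
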