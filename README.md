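# bubblegum

Molecular-signature extraction and exhaustive pairwise GSEA with map-wide
multiple-testing correction and a bubble-matrix visualization.

## The problem

Gene Set Enrichment Analysis (GSEA) tests whether a predefined set of genes
is concentrated toward the top or bottom of a list of all genes ranked by
differential expression between *two* conditions. Real studies rarely have
two conditions: a dataset with *n* phenotypes (cell types, treatments,
disease states) has *n·(n−1)* directed pairwise comparisons, and running
GSEA serially over all of them raises two problems that this package solves:

1. **Where do the gene sets come from?** The most informative sets are often
   *home-made* signatures — the genes specifically high in one phenotype
   versus the others, extracted from an independent dataset. The `genesign`
   module extracts such signatures with five statistics and proper
   permutation-based error control.
2. **How is significance assessed across the whole matrix of results?**
   Testing every set against every comparison inflates false positives. The
   `bubblemap` module pools the permutation null across all comparisons and
   controls the false discovery rate over the entire gene-set × comparison
   family, then draws the result as a matrix of bubbles.

A classic application is cross-species comparison: extract cell-type
signatures from mouse immune cells, then ask in which human cell types each
signature is enriched — repetitive enrichment patterns across all
comparisons identify homologous cell types without any cross-platform
normalization.

## The statistics

**Signature extraction.** For a contrast of test classes *T* versus
reference classes *R*, per-gene scores are one of:

- `min-vs-max` — min(test values) / max(reference values); very stringent,
  works with few replicates, no permutation machinery;
- `mean-ratio` — mean(T) / mean(R) on pooled samples;
- `min-pairwise-mean-ratio` — min over class pairs (t, r) of mean_t/mean_r
  (provably ≤ the pooled ratio: more stringent);
- `snr` — (mean_T − mean_R)/(sd_T + sd_R), sample sd with a relative floor;
- `min-pairwise-snr` — min over class pairs of the per-pair SNR.

For the permutation-based methods, one-sided p-values come from shuffling
the sample → class assignment (preserving replicate counts):
p = (b+1)/(m+1), where *b* counts permuted scores ≥ the observed score over
*m* permutations — the estimator never returns 0, and the null is enumerated
exhaustively when the assignment space is small. Adjustment is
Benjamini–Hochberg (independence) or Benjamini–Yekutieli (arbitrary
dependence; extra factor c(m) = Σ 1/k).

**Pairwise GSEA.** Genes are ranked by signal-to-noise; the enrichment score
ES is the signed maximum deviation of the weighted running sum
(hits add |metric|^w normalized to unit mass, misses subtract 1/(N−hits));
NES = ES / mean |same-sign null ES|. Null distributions come from random
same-size gene sets (default) or from sample shuffling (requires ≥ 5
replicates per class). The normalized nulls of *all* cells are pooled per
sign, each cell's p-value is the (b+1)/(m+1) tail count in that pool, and
B–Y over the whole family yields the map-wide FDR. In the figure, each cell
is a circle: area ∝ |NES|, color = enriched side, intensity = significance;
cells above the display FDR threshold are empty circles.

## Worked example

Everything runs offline on a synthetic fixture with planted signatures
(7 phenotypes × 3 replicates, 2,000 genes, six 50-gene blocks at a four-fold
effect; the seventh phenotype has no block and acts as a negative control):

```sh
bubblegum simulate --out-dir demo/fixture --seed 5
bubblegum genesign --expression demo/fixture/expression.gct \
    --cls demo/fixture/phenotypes.cls --method min-vs-max --fold 1.5 \
    --out-dir demo/signatures
bubblegum bubblemap --expression demo/fixture/expression.gct \
    --cls demo/fixture/phenotypes.cls --gmt demo/fixture/sets.gmt \
    --nperm 1000 --seed 7 --min-size 10 --filter humS --out-dir demo/map
```

which prints:

```
wrote fixture to demo/fixture
wrote 7 signature(s) (1 empty) to demo/signatures
computed 378 cells (21 unique comparisons); output in demo/map
```

`7 signature(s) (1 empty)`: one absolute signature per phenotype; the
negative-control phenotype correctly yields an empty signature. `378 cells`:
18 gene sets (6 planted fingerprints + 12 random padding sets) × 21 unique
comparisons; the mirrored orientations (42 directed views) are sign-flipped
copies, not recomputed. `demo/map/cells.tsv` holds per-cell ES, NES, pooled
p, map-wide FDR and the enriched side; `demo/map/bubblemap.svg` shows the
fingerprint rows only (`--filter humS`), where each planted fingerprint
appears as a row of large, saturated bubbles colored by its own phenotype —
the repetitive pattern that identifies the matching class in every
comparison.

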