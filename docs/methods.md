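# Methods

This note documents the statistical model implemented by the package, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic benchmark does and does not demonstrate.

## Signature extraction (`genesign`)

A signature for a contrast (test classes *T*, reference classes *R*) is the
list of genes scored strictly above a fold threshold, optionally also
required to pass an FDR threshold, sorted by score descending. All ratio
statistics are defined on **linear-scale** intensities (a `log2_input` flag
exponentiates at load), because fold-change thresholds such as "> 2×" are
linear-scale concepts while common normalization pipelines emit log2 values.
Multi-class test or reference groups are **pooled at the sample level** for
the pooled statistics (`mean-ratio`, `snr`); the `min-pairwise` variants
instead take the worst case over all (test class, reference class) pairs,
which makes them provably at least as stringent (the minimum pairwise ratio
is bounded by the ratio of pooled means when replicate counts are equal).

Signal-to-noise uses the sample standard deviation (ddof = 1) with the floor
`sd ← max(sd, 0.2·|mean|, 0.2·δ)` where δ is the smallest positive value in
the matrix. The floor is the GSEA-ecosystem convention; it prevents zero
denominators for flat genes (a gene constant across samples scores exactly
0) and stabilizes low-variance genes.

### Permutation p-values

The null distribution is built by shuffling the sample → class assignment,
restricted to the samples of the contrast and preserving every class's
replicate count. P-values are one-sided (test > reference, because a
signature is by definition the genes *higher* in the test group) and use the
never-zero estimator **p = (b + 1)/(m + 1)**, with *b* the number of
permuted scores ≥ the observed score out of *m* permutations. The smallest
attainable value is therefore 1/(m+1): with few samples the number of
distinct permutations is small and a naive b/m estimator would report
impossible zeros, which would break any subsequent FDR step. When the number
of distinct assignments is ≤ the requested permutation count, the null is
enumerated exhaustively (identity assignment included in the count);
otherwise assignments are sampled uniformly with replacement.

By default each gene is compared to **its own** permuted scores (gene-wise
null). A `pooled` option compares each gene to the permuted scores of all
genes combined, which lowers the attainable p-value floor from 1/(m+1) to
1/(m·G+1) at the cost of assuming the per-gene score distributions are
exchangeable under the null.

Under a global null the sampled p-values are uniform on their support; the
test suite checks this with a Kolmogorov–Smirnov statistic on a 5,000-gene
two-class null dataset (8 replicates per class so the assignment space is
large; observed KS ≈ 0.01).

### Multiple testing

`adjust_pvalues` delegates to the standard step-up implementations
(Benjamini–Hochberg, and Benjamini–Yekutieli with the factor
c(m) = Σ_{k≤m} 1/k). B–Y is the package default because permutation scores
of co-regulated genes are dependent. One caveat matters in practice and is
exercised by the benchmark: with *r* replicates per class the permutation
floor is roughly 1/(number of distinct test subsets), e.g. ≈ 1/1330 for 3
test samples among 21. B–Y at target q over a family of G genes requires
p ≤ q·k/(G·c(G)) for k discoveries, which with G = 2000, k = 50, q = 0.05
demands p ≤ 1.5·10⁻⁴ — *below the attainable floor*. In that regime B–Y
cannot declare anything significant no matter how strong the effect; this is
a property of the replicate count, not of the implementation. The
planted-recovery benchmark therefore evaluates sensitivity with B–H, which
is valid there because the simulated genes are independent by construction;
it uses 50,000 sampled permutations so that the Monte-Carlo spread of p̂
near the B–H cutoff does not erode sensitivity.

## Pairwise GSEA (`gsea`, `bubblemap`)

Genes are ranked by signal-to-noise (left vs right; the same sd floor),
descending, ties broken by input row order. The enrichment score of a set
with *k* members present in the data is the signed maximum deviation of the
running sum that adds `|metric|^w / N_R` at hits (N_R normalizes the hit
mass to 1) and subtracts `1/(N−k)` at misses. Defaults: weight w = 1 (the
"weighted" scheme; w = 0 reduces exactly to the classic two-sample
Kolmogorov–Smirnov statistic, which the tests verify), set-size filter
[15, 500] (sets are intersected with the dataset first; out-of-range sets
raise a distinct skip signal, not an error). These are GSEA-ecosystem
conventions, configurable on every entry point.

Numerical conventions: only running-sum values adjacent to hits can be
extrema (the sum is linear in between), so ES is computed by an O(k) scan;
when the maximal positive and negative deviations tie in magnitude (within
1e−9, absorbing summation-order rounding), the deviation occurring earliest
in the ranked list is taken. A set containing every ranked gene is a
degenerate input (error); members absent from the dataset are dropped and
reported via `set_size_used`.

**Nulls.** Gene-set permutation (default) draws random same-size member sets
without replacement; sample permutation shuffles the pair's labels and
re-ranks, and requires at least 5 replicates per class (an explicit override
exists for exploration). Random member sets are drawn in a canonical
lexicographic gene order and then mapped to list positions, so the drawn
*gene sets* depend only on the seed and the gene universe: swapping a
comparison's two classes reverses the ranked list, negates every metric
bitwise, and negates ES and NES to within 1e−12 (summation order is the only
difference). Because a gene-set-permutation null depends only on the ranked
list and the set size, cells of one comparison that share a size share one
null draw, seeded by (run seed, pair index, size) — deterministic and
independent of which other sets are in the collection.

**NES and the map-wide FDR.** NES divides ES by the mean magnitude of the
same-sign null scores (undefined, and flagged, if no null score shares the
sign — practically unreachable at ≥ 100 permutations). The per-sign
*normalized* nulls of all cells are pooled across the entire map; each
cell's p-value is the (b+1)/(m+1) tail count of |NES| in its same-sign pool.
Pooling normalized (rather than raw) null scores is what makes scores of
different set sizes and comparisons commensurable in one pool. B–Y is then
applied over the family of all unique cells. Each unordered pair is computed
once and mirrored by sign-flip for display: GSEA statistics are exactly
antisymmetric, so computing both orientations would double the runtime and,
worse, duplicate every test in the FDR family. The family is therefore
gene sets × unordered pairs.

On fully null maps (6 exchangeable classes × 3 replicates, 2,000 genes, 40
random sets of 15–50 genes, 500 permutations, 20 Monte-Carlo repeats) the
mean fraction of cells at map-wide FDR < 0.05 is far below 0.05 — B–Y under
a pooled null is conservative — and the map-wide adjustment is on average at
least as strict as adjusting within each comparison separately.

## The synthetic generator (`simulate`)

Log2 intensities are `baseline + effect·[planted] + N(0, noise_sd)`; stored
values are `2^log2` (strictly positive, log-normal — the structure of
RMA-normalized microarray data). Defaults mirror a small multi-phenotype
profiling study: 7 classes × 3 replicates, 2,000 genes, six disjoint
50-gene blocks at effect 2.0 log2 (four-fold), noise_sd 0.5 log2,
baseline 7.0 log2. The seventh class has no block (negative control).
`simulate_gene_sets` builds one fingerprint set per block (names carry the
filterable infix `humS`) plus, by default, twice as many randomly drawn
padding sets — mixing in random sets keeps the multiple-testing family
mostly null, which the conservative correction needs to behave sensibly.

What the generator does **not** model: probe-level effects, batch and
platform differences, cross-species ortholog mapping noise, correlated gene
modules beyond the planted blocks, and intensity-dependent variance.
Passing the planted-recovery benchmark therefore shows that the statistics
recover clean block structure at realistic noise; it does not certify
performance on real cross-platform data.

## Benchmark results computed by `scripts/acceptance.py`

All quantities are recomputed from the seed at run time: the 42 directed
comparisons of 7 phenotypes; the replicate floor of 5 for sample
permutation; the worked ES example (0.75); max deviation of ES and of BH/BY
from brute-force oracles; the KS uniformity statistic; the null-map
false-positive fraction at FDR < 0.05 (10 null maps); the fraction of
fingerprint × own-class comparisons at signed NES > 0 and FDR < 0.10
(expected 1.0); and the sensitivity of mean-ratio signatures (fold > 2,
B–H FDR < 0.05, 50,000 permutations) for planted genes, in percent.
Problem sizes match the defaults above; the null-map repeat count (10 in
the script, 20 in the test suite) and permutation counts are chosen so a
full run completes in minutes on one CPU.

## Known limitations

- Sample-permutation nulls re-rank the full matrix per permutation (no
  vectorized path); with many permutations on large matrices the gene-set
  permutation mode is strongly preferred.
- Leading-edge subsets and enrichment ("mountain") plots are out of scope.
- The pooled-null design means a cell's p-value depends (weakly, through
  the pool) on which other sets and comparisons are in the run; removing a
  set changes surviving FDRs only through the family size and pool, and on
  the benchmark fixtures never raises them.
- Heatmap and PNG rendering go through matplotlib and are not guaranteed
  byte-stable across matplotlib versions; the SVG bubble map is emitted
  directly and is byte-stable.
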