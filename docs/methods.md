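# Methods

## Problem and overall design

`subtypelink` asks whether molecular subtypes of cancers arising in
*different* tissues share transcriptional programs. Given several cohorts
(genes × samples expression matrices with a subtype label per sample), it

1. merges probes to genes (averaging), median-centers each gene within each
   cohort, and intersects gene universes across cohorts;
2. scores every sample against a gene-set collection with single-sample
   GSEA (ssGSEA), producing a *pathway profile* alongside the
   *transcriptional profile* (the centered expression vector);
3. computes Spearman rank correlation between every cross-cohort sample
   pair on either profile, and summarizes each subtype pair by the median
   correlation over its sample pairs;
4. builds a subtype dendrogram ("phylogeny") by average linkage on the
   dissimilarity `1 − median rho`;
5. runs one-vs-rest GSEA per subtype per cohort with a phenotype-permutation
   null, retains gene sets at FDR q < 0.25, and tabulates how many subtypes
   and tissues each retained set recurs in;
6. pools all cohorts' pathway profiles, clusters samples by average linkage
   on `1 − Spearman`, cuts the dendrogram at the root into two groups, and
   tests each subtype for overrepresentation in a group (chi-squared).

## Statistics

**Spearman correlation.** Pearson correlation of average-rank vectors
(ties get the mean of their rank range). A constant vector has zero rank
variance and raises an error rather than returning a silent NaN.

**Subtype similarity.** Entry (s, t) is the median of the pairwise sample
correlations with one sample in s and one in t. On the diagonal
(within-cohort, s = t) only unordered distinct pairs count — self-pairs
(rho = 1) would bias the medians upward. Cross-cohort entries use only
cross-cohort sample pairs.

**ssGSEA score.** For one sample, genes are ranked by decreasing
expression (ties broken by gene-id order). The score of a set S is the sum
over ranked positions of `P_in − P_out`, where `P_in` is the cumulative
normalized in-set weight (`w_i = |expr_i|^alpha`, or 1 at `alpha = 0`) and
`P_out` the cumulative fraction of out-of-set genes. Positive scores mean
the set is coordinately upregulated in that sample. The implementation
uses the closed form `sum_in w_i (G − pos_i)/W − sum_out (G − pos_j)/(G − |S|)`
(0-based positions), which equals the position-by-position sum exactly;
the explicit walk survives as an independent test oracle. Scores are used
raw — no rescaling across sets.

**GSEA.** Ranking metric per the cohort's scale dialect: signal-to-noise
`(mu_in − mu_rest)/(sd_in + sd_rest)` for absolute-intensity cohorts, with
each class sd floored at `0.2·|mu|` of that class (and at 0.2 when both sd
and mean vanish) so constant genes stay finite; plain difference of class
means for log-ratio cohorts, where ratios are already fold changes. The
enrichment score is the signed maximal deviation of the weighted KS
running sum (hit increments `|metric|^p / W`, miss decrements
`1/(N − |S|)`; `p = 1` by default). The permutation null permutes the
one-vs-rest phenotype labels (`n_perm = 1000`); NES divides ES by the mean
magnitude of same-sign null ES of the same set; nominal p is the
same-sign null tail fraction; FDR q is the ratio of null to observed tail
fractions on sign-separated NES pools, with a running-minimum enforcement
so a more extreme NES never receives a larger q, capped at 1. Retention
keeps rows with q strictly below 0.25; a set is thereby retained exactly
when it is significant in at least one subtype, and recurrence tabulation
counts those rows directly.

GSEA runs on the *uncentered* expression values: the signal-to-noise floor
`0.2·|mu|` is meaningless after median-centering (per-gene means near 0),
while correlation and ssGSEA default to centered input (configurable via
`ssgsea.input: centered|raw`).

**Average linkage.** Unweighted UPGMA: merge the cluster pair with the
smallest mean leaf-pair distance, at exactly that mean (Lance–Williams
update, cross-checked in tests against a from-scratch re-averaging oracle
and scipy). Ties on the minimum are broken by the lexicographically
smallest pair of cluster labels (a cluster is labeled by its smallest leaf
label), making topologies reproducible where generic implementations
depend on input order. Merge heights are provably non-decreasing, so the
Newick export (branch length = parent height − own height) is ultrametric.

**Two-group split and enrichment.** The pooled pathway-profile dendrogram
is cut at the final merge; K1 is the side holding the lexicographically
smallest sample id. Each subtype's 2×2 table (subtype membership × group
membership) gets a Pearson chi-squared test without continuity correction;
when any expected cell is below 5 the test falls back to Fisher's exact
test and is flagged in the output. The enriched group is the one where
the subtype's observed count exceeds its expectation under independence.

## Tunable parameters

| key | default | meaning |
| --- | --- | --- |
| `min_common_genes` | 5000 | minimum overlap with the running gene set before a cohort is excluded (500 in the synthetic preset, whose universes hold 2000 genes) |
| `ssgsea.alpha` | 0.25 | ssGSEA rank weighting exponent |
| `ssgsea.min_set_size` | 5 | sets smaller than this after intersection are dropped |
| `ssgsea.input` | centered | which matrix feeds the pathway profile |
| `gsea.n_perm` | 1000 | phenotype permutations (hard minimum 100) |
| `gsea.weight_p` | 1.0 | ES weighting exponent |
| `gsea.q_threshold` | 0.25 | FDR retention cutoff (strict `<`) |

The GSEA class-size floor is 3 samples (subtype skipped below it, warning
below 7). Seeds fan out from one run seed by fixed offsets per stage and
per (cohort, subtype), so results are independent of input order.

## Synthetic data

The generator emulates normalized multi-cohort microarray data: per-gene
baselines `mu_g ~ N(8, 1)` on the log2 scale shared across cohorts
(shifted to 0 for two-color log-ratio cohorts), i.i.d. Gaussian noise
(`noise_sd = 1`), partially overlapping gene universes (90% of each
cohort's genes drawn from a shared global universe, the rest private), and
planted *programs*: 50-gene modules added (±delta, `delta = 1`) to the
samples of designated (cohort, subtype) members. A program shared by
subtypes of two cohorts makes them cross-tissue partners; the module
doubles as that subtype's planted dysregulated gene set. The default
preset is 3 cohorts × 60 samples × 2000 genes with 3 equal subtypes each
and 4 programs; the two-group preset instead assigns every subtype to one
of two planted groups with mirrored up/down modules. `null_mode` zeroes
all effects for type-I-error checks.

What the generator does **not** emulate: probe-level structure, batch and
platform effects, correlated gene-gene noise, heavy-tailed intensities,
unbalanced subtype prevalences or overlapping gene-set collections of
MSigDB's density. Passing tests therefore demonstrate correctness of the
statistics and recovery of planted structure under idealized noise — not
performance on any real cohort.

## Numerical choices and degenerate inputs

- Metric and expression ties break by lexicographic gene id (genes are
  sorted before stable argsorts), making every ranking reproducible.
- When the running sum's largest positive and negative deviations tie to
  within 1e-9, the positive ES is reported; the walk and the vectorized
  batch kernel apply the same rule so they agree bitwise.
- All-zero ES weights (every in-set gene has metric 0) fall back to the
  unweighted statistic instead of dividing by zero.
- A gene set covering the whole universe, an empty overlap at the
  single-score level, constant profiles for correlation, and non-finite
  dissimilarities all raise typed errors; small sets and constant pathway
  columns are dropped with warnings.
- Expression input rejects missing/non-numeric cells rather than imputing.
- Tabular outputs are written with 10-significant-digit formatting; reruns
  with the same config and seed are byte-identical.

## Design choices made where the design was open

- **Gene-universe intersection** is greedy in input order: a cohort whose
  overlap with the running intersection falls below `min_common_genes` is
  excluded (recorded, warned). Determinism was preferred over optimal
  subset selection; if the *first* cohort is the outlier the rule excludes
  the others instead, a documented limitation.
- **ssGSEA monotonicity**: raising all in-set genes by a common amount
  provably never decreases the score at `alpha = 0`; at `alpha > 0` the
  `|expr|^alpha` re-weighting admits tiny counterexamples when ranks do
  not move, so the property is asserted only for the unweighted score.
- **Retention semantics**: the q filter drops individual non-significant
  (cohort, subtype, set) rows; set-level retention ("significant in at
  least one subtype") is implied, and recurrence counts are taken over the
  significant rows only.
- **Recurrence classes**: tissue-specific = hits in exactly one tissue;
  common = hits in at least five tissues; everything else intermediate.
- **Two-color orientation** is assumed tumor-over-reference (higher value
  = higher tumor expression).

## Problem sizes

The shipped presets (2000 genes, 180 samples, ≤ 204 gene sets, 1000
permutations) were chosen so that the complete pipeline, the test suite
and `scripts/acceptance.py` each run in well under a minute to a few
minutes on a single core while leaving every planted effect comfortably
detectable; all sizes scale up through the design dataclasses.

## Known limitations

- No batch correction, quantile normalization or variance filtering; the
  pipeline assumes cohorts are individually normalized upstream.
- FDR q-values are permutation estimates; at `n_perm = 1000` their
  granularity is ~1e-3 and very small q-values saturate at 0.
- The phylogeny is a UPGMA dendrogram of median correlations — a summary
  of similarity, not an evolutionary inference.
- Probe-to-gene mapping must be supplied; no annotation retrieval.
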