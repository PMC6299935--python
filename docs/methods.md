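# Methods

This note documents the statistics implemented in `depath`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators emulate, and the package's known limitations.

## Pre-processing

**Filtering.** Genes are kept when their counts-per-million value
(`CPM[i,j] = counts[i,j] / library_size[j] × 10^6`) reaches
`cpm_threshold` (default 0.5) in at least `min_samples` samples (default
1). Filtering happens on the counts scale, before transformation and
after any ID conversion/collapse, so the collapse step sees every
measured row.

**Transformation.** The default transform is a started log,
`log2(CPM + c)` with pseudocount `c = 4`. The pseudocount bounds the
variance of low-count genes: counts near zero map to values near
`log2(4) = 2` with small spread instead of diverging. This is a
deliberately simple, dependency-free variance-taming transform; it is
*not* a substitute likelihood model — count-model transforms (rlog/VST)
and count-based DE (DESeq2/edgeR) remain the right tools when those
inferences matter, and their output tables can be imported directly.

**Skew detection.** Raw counts have strongly right-skewed pooled value
distributions; log-transformed data do not. The pooled sample skewness
(third standardized moment, biased estimator g1) is computed over all
matrix entries; when it exceeds `skew_threshold = 2` on non-negative
data, the pipeline enforces the log transform even if the user disabled
it. The threshold is a heuristic chosen so that typical NB-distributed
counts (skewness ≫ 2) trigger it while log-scale data (|skewness| < 1)
never do; it is configurable. A constant matrix is defined as skewness 0.

**Library-size QC.** Sequencing depth that differs systematically
between sample groups confounds every downstream fold-change. The QC
step runs a one-way ANOVA of per-sample total counts grouped by the
design factor and warns at `p < anova_alpha = 0.05`. With identical
group totals the F statistic degenerates; p is reported as 1.

## Gene-ID handling

IDs are matched case-insensitively after stripping a trailing version
suffix (`\.\d+$`), because versioned Ensembl/RefSeq ids are common and
version mismatches between a user's quantification and a mapping table
should not lose genes; both behaviors can be disabled. Species detection
counts the distinct query ids matched per species and ranks species by
that count (ties alphabetical). After conversion, rows that share a
canonical id are collapsed to the single row with the largest sample
standard deviation (ddof = 1) across samples — the most informative
measurement; SD ties keep the earlier row so file order is deterministic.
A source id that maps to several canonical ids for the chosen species is
resolved to the alphabetically first target, which keeps conversion from
ever increasing the row count. Unmatched ids are kept verbatim by
default (so unannotated genomes can still flow through EDA and DE) or
dropped on request.

## Exploratory analysis

Genes are ranked by standard deviation across samples and the top slice
(default 1000; more for complex multi-group designs) feeds clustering.
Hierarchical clustering centers each gene, uses `1 − Pearson r` distance
and average linkage — the common default for expression heatmaps;
Euclidean/complete are available. A zero-variance item has undefined
correlations; they are treated as 0 (distance 1) with a warning. K-means
standardizes each gene to mean 0, SD 1 (so clusters capture profile
shape, not magnitude), runs 10 restarts with a fixed seed, computes the
within-group sum-of-squares curve for k = 1..15 as an elbow diagnostic,
and relabels clusters A, B, … by descending size so names are stable
across runs. PCA treats samples as observations and genes as centered
variables; loadings are unit-norm per component with the
largest-magnitude loading made positive (a deterministic sign
convention), and variance fractions are eigenvalue shares.

## Differential expression

The built-in test is a per-gene Welch two-sample t-test on the
transformed (log2) data, `log2FC = mean(A) − mean(B)`, with BH-FDR
across genes. It assumes approximate normality of log-scale expression
within groups and needs ≥ 2 samples per group; genes with no variance in
either group get p = 1. Thresholding uses strict inequalities —
`fdr < fdr_cut` and linear fold-change `> fc_cut` (default 0.1 and 2) —
so boundary genes are not called. This test exists to make the pipeline
end-to-end runnable and calibrated (its null p-values are approximately
uniform on NB simulations); for publication-grade DE on counts, import a
DESeq2/limma result table instead.

## Enrichment

For a query list against a background universe, each gene set S is
scored with the hypergeometric upper tail
`p = P(X ≥ k), X ~ Hypergeom(N, K, n)` where `N` is the background size,
`K = |S ∩ background|`, `n = |query ∩ background|`, and `k` the overlap.
BH-FDR is applied per collection, matching how per-database result
tables are usually reported. Sets with effective size outside
[15, 2000] are not tested (configurable). The default background is the
set of processed-matrix genes that appear in at least one set of the
collection — genes the collection can possibly know about; the full
collection universe is available as an option. The choice of universe
materially changes p-values and should be stated in any report.

Enriched-term redundancy is summarized with the overlap-coefficient
distance `1 − |A∩B| / min(|A|, |B|)` computed on set members restricted
to the query list; "fraction of shared genes" is ambiguous between
min/union denominators, so Jaccard is available as an option. The
distance feeds an average-linkage tree (exported as Newick) and a term
network with an edge wherever the overlap coefficient reaches 0.5.

## Pathway activity

The parametric gene-set statistic: given a per-gene score vector
(log2 fold-changes) with global mean μ and sample SD σ (ddof = 1, the
population/sample distinction being negligible at thousands of genes),
a set with m members and member mean S_m scores

    Z = (S_m − μ) · √m / σ,

approximately N(0,1) when the set is an exchangeable random draw —
two-tailed p from the standard normal, BH-FDR across sets. In
absolute-value mode the statistic is computed on |log2FC|, detecting
pathways that are strongly *regulated* in both directions rather than
coherently shifted.

Per-sample activity applies the same statistic column by column after
centering each gene on its row mean across samples, so each column's Z
measures that sample's deviation from the average profile. Centering on
the row mean (rather than a designated control group) keeps the score
symmetric in the samples and matches the red/blue contrast-heatmap
reading; a control-referenced variant would shift all columns by a
constant per set.

Differentially active pathways are found by a one-way ANOVA of each
set's per-sample Z across the design groups, BH-FDR across sets, an
`fdr < 0.05` cut, and ranking the survivors by the standard deviation of
their per-sample Z (descending, ties by name). The SD ranking surfaces
the pathways with the largest between-group swing among those that are
significant; ranking by the SD of group means is available as an
alternative interpretation.

PCA-loading pathway analysis treats the loadings on each gene as
expression data: per component, each set's member loadings are tested
against the global mean loading with a one-sample t-test, BH-adjusted
within the component; the top 5 sets per component are reported for the
first 5 components, skipping sets already reported for an earlier
component, with labels carrying FDR then component id.

## Promoter motif enrichment

PWMs (MEME-minimal or 4-row count matrices) are converted to
probabilities with a pseudocount of 0.01 added to every cell before
per-position normalization. Scores are log2-odds against a 0-order
background; the default background is the pooled base composition of
the supplied promoters, symmetrized over complementary bases (A with T,
C with G) so that scores are invariant to which strand a promoter was
reported on. For every promoter and motif the best score over both
strands and all offsets is recorded; `N` bases contribute 0, and
promoters shorter than a motif get a missing value. Enrichment in a
gene list is a Welch t-test of best scores, list vs all other
promoters, one-sided (greater) because enrichment means *higher*
binding scores — two-sided is selectable — with BH-FDR across motifs
and an output table (motif, TF, family, FDR) ready for reporting.
Scores are raw maxima: 300 nt and 600 nt promoters are not
length-normalized (longer sequences have stochastically higher maxima),
so enrichment lists should compare promoters of one length; the
promoter length is the analyst's responsibility.

## Synthetic data

`simulate_counts` draws counts from a negative binomial with
`var = μ + α·μ²` (gamma–Poisson mixture, default dispersion α = 0.1 —
a typical bulk RNA-seq replicate dispersion), gene means log-normal
(default ln-scale mean 4, SD 1.5, i.e. median ≈ 55 counts with a long
right tail), 2 groups × 5 samples, and 5% of genes shifted ±2 log2
units in non-reference groups — a well-powered two-condition
experiment. Generators for gene sets, promoters (i.i.d. uniform ACGT
with planted consensus occurrences) and mapping tables are similarly
seed-deterministic: the same spec and seed reproduce byte-identical
files.

What the simulations do **not** emulate: batch effects, GC and length
bias, correlated genes (co-expression), outlier samples, realistic
promoter composition (CpG islands, repeats), or annotation errors in
mapping tables. Passing tests on these fixtures therefore demonstrate
correctness and calibration of the statistics under their stated
assumptions — not robustness to the full messiness of real data.

## Numerical and design choices

- SDs use the sample (n−1) denominator throughout; ties in SD-based
  selection keep input order.
- BH-FDR via `statsmodels.stats.multitest.multipletests(method="fdr_bh")`
  everywhere a p-value family is adjusted.
- Hypergeometric tails via `scipy.stats.hypergeom.sf(k−1, …)` — exact to
  machine precision (verified against exhaustive enumeration).
- Degenerate inputs are defined, not crashed on: constant matrices have
  skewness 0; zero-variance genes get p = 1 in DE and ANOVA; constant
  samples produce missing correlations; all-N promoters score 0.
- All orderings (enrichment tables, pathway rankings, cluster labels)
  have deterministic tie-breaks so seed-identical reruns are
  byte-identical.
- Problem sizes in the test-suite simulations (2000 genes, ≤ 1000 sets,
  ≤ 500 motifs, 100 promoters) are chosen as the smallest sizes at which
  the calibration and power properties are statistically meaningful.

## Limitations

- The Welch DE test ignores the mean–variance relationship of counts;
  power on low-count genes is below what count models achieve, and
  fold-change estimates of weakly expressed genes are shrunk by the
  started-log pseudocount.
- The parametric Z assumes gene-level scores are exchangeable across
  sets; inter-gene correlation inside real pathways inflates |Z|
  somewhat, as it does for all parametric set statistics.
- The enrichment universe default is pragmatic, not canonical; results
  depend on it.
- No annotation databases ship with the package: mapping tables, GMT
  collections, promoters and PWMs are user-supplied inputs.
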