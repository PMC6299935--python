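# depath

Scriptable differential-expression and pathway-analysis toolkit for
gene-level expression matrices (bulk RNA-seq, microarray, or any
genes × samples table of counts or normalized values).

After read mapping and quantification, a typical transcriptomics analysis
still requires a long chain of steps — QC, filtering, transformation,
gene-ID harmonization, exploratory analysis, differential expression, and
several flavors of gene-set analysis — usually scattered across many
tools. `depath` packages that analytic chain as a plain Python library
with a thin command-line interface, so the whole workflow is reproducible
from a single config file and testable offline against synthetic data.

## What it computes

- **Pre-processing & QC** — low-expression filtering at a CPM threshold
  (default: keep genes with ≥ 0.5 counts per million in at least one
  sample), a started-log transform log2(CPM + 4), skew detection that
  enforces log transformation on raw right-skewed data, and a one-way
  ANOVA of per-library total counts across sample groups that warns when
  sequencing depth is confounded with the design.
- **Gene-ID conversion** — species detection by counting matched ids per
  species in a user-supplied mapping table, conversion to a canonical
  (Ensembl-style) namespace, and collapsing of duplicate ids by keeping
  the row with the largest standard deviation.
- **Exploratory analysis** — top-variance gene selection, hierarchical
  clustering (1 − Pearson correlation, average linkage), k-means with a
  within-group sum-of-squares elbow curve, sample correlation matrices,
  and PCA.
- **Differential expression** — a per-gene Welch t-test fallback with
  Benjamini–Hochberg FDR, thresholding at FDR < 0.1 and fold-change > 2
  (both configurable), Venn-region counts of DEG lists, and import of
  external DE tables (DESeq2, limma, cuffdiff) to drive downstream steps.
- **Enrichment** — hypergeometric over-representation of a gene list in
  GMT gene sets with BH-FDR, plus redundancy summarization of enriched
  terms by overlap-coefficient distance (clustering tree + term network).
- **Pathway activity** — the parametric gene-set statistic
  `Z = (S_m − μ)·√m / σ` on fold-changes (PAGE), per-sample activity
  matrices on row-centered expression (PGSEA-style), a one-way ANOVA of
  per-pathway Z across sample groups with FDR cut and ranking by the
  standard deviation of Z, an absolute-fold-change mode, and pathway
  analysis of PCA loadings via per-set one-sample t-tests.
- **Promoter motif enrichment** — best log2-odds PWM score per promoter
  (both strands, all offsets), then a one-sided Welch t-test comparing a
  gene list's best scores against all other promoters, FDR-corrected
  across motifs.
- **Synthetic data** — negative-binomial count simulation with planted DE
  genes, gene-set collections with planted enriched sets, promoters with
  planted motif occurrences, and mock species mapping tables, all
  seed-deterministic.

## Worked example

Generate a synthetic bundle (2000 genes, 2 groups × 5 samples, 5% of
genes shifted by 2 log2 units, a 50-gene planted set, promoters with a
planted motif) and run the whole pipeline:

```sh
depath simulate --out-dir demo/bundle --n-genes 2000 --n-samples-per-group 5 --seed 1
depath all --matrix demo/bundle/counts.tsv --design demo/bundle/design.tsv \
    --gmt demo/bundle/genesets.gmt --promoters demo/bundle/promoters.fa \
    --pwms demo/bundle/pwms.txt --de-factor group \
    --de-level-a g2 --de-level-b g1 --out-dir demo/out
```

The run prints one line per stage (`completed: preprocess` … `completed:
motif`) and exits 0. `demo/out/pipeline.log` records the QC decisions:

```
[preprocess] library-size ANOVA on 'group': p=0.04823 warning=True
[preprocess] low-expression filter removed 0 genes
[deg] group:g2_vs_g1: 41 up, 45 down
```

Here the simulated libraries happen to differ in depth between groups
(p < 0.05), so the QC warning fires — on real data this means depth is
confounded with condition and fold-changes should be interpreted
carefully. The Welch test then calls 86 DEGs at FDR < 0.1 and FC > 2.

`demo/out/enrichment_down.tsv` shows the planted set recovered as the top
enrichment among the down-regulated genes — 25 of its 50 members among
the 40 down-regulated genes present in the 1631-gene background, an
overlap that is essentially impossible by chance:

```
set_name         k   K   n   N     p_value      fdr
planted_set      25  50  40  1631  3.69164e-31  1.88274e-29
random_set_0028  3   36  40  1631  0.0557937    1
```

`demo/out/pathway_activity.tsv` carries the per-sample activity Z-scores
of the pathways that survive the ANOVA FDR cut, ranked by the spread of
their Z across samples; the planted pathway is consistently active in
group 1 and suppressed in group 2 (Z ≈ +2 vs −2, ANOVA p = 1.3e-4).

Every output table starts with a `# depath <version> | …` header that
records the resolved parameters, and `resolved_config.txt` can be fed
back via `--config` to reproduce the run byte-for-byte.

## Library use

```python
from depath import (read_expression_matrix, read_design, filter_low_expression,
                    transform_counts, welch_de, apply_thresholds,
                    read_gmt, hypergeometric_enrich)

matrix = read_expression_matrix("counts.csv")
design = read_design("design.csv", matrix)
filtered, n_removed = filter_low_expression(matrix)
expr = transform_counts(filtered)
de = welch_de(expr, design, "Treatment", "IR", "mock")
up, down = apply_thresholds(de, fdr_cut=0.1, fc_cut=2.0)
sets = read_gmt("go_bp.gmt")
table = hypergeometric_enrich(down, sets, background=expr.gene_ids)
```

See `docs/methods.md` for the statistical model behind each stage, the
meaning and defaults of every tunable parameter, and known limitations.
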