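# itersig

Iterative feature-selection clustering and signature analysis for TPM-scale
single-cell RNA-seq, with downstream unique-gene filtering, receptor–ligand
cell–cell interaction inference and bulk-tissue signature validation.

## The problem

IL-33 drives proliferation of bile-duct epithelium, and innate immune cells
in the liver and extrahepatic bile duct (EHBD) are suspected intermediaries.
Sorting CD45⁺ lineage-negative mononuclear cells from treated mice and
profiling them one cell at a time yields small TPM matrices — tens of cells
per treatment group — in which the latent cell classes, their
tissue restriction, their marker genes and their potential cross-talk all
have to be inferred computationally. This package implements that analysis
chain as a tested, reusable library, and ships a synthetic-data generator
that plants known classes, markers and ligand–receptor pairs so every stage
can be validated against ground truth without any external download.

## The method

Cells are clustered by a three-step loop on log₂(TPM+1) values:

1. **Feature selection.** Iteration 1 uses the leading principal components
   covering 80% of variance; later iterations use the pooled top-ranked
   genes of the previous iteration's classes.
2. **Clustering.** Agglomerative average linkage (UPGMA) on the
   Pearson-correlation distance d(i,j) = 1 − r(xᵢ, xⱼ) between cells; the
   flat cut k maximises mean silhouette width, and each large cluster may
   be split once more into subclusters.
3. **Signature ranking.** For each class c, genes are ranked by a one-sided
   Wilcoxon rank-sum test (class vs rest) and by fold change
   FC(g) = (mean TPM in c + 1)/(mean TPM elsewhere + 1), at cluster and —
   when present — subcluster level. The Rank Product
   RP(g) = (∏ᵢ rankᵢ(g))^(1/k) integrates the k ≤ 4 rankings; each class's
   top-200 genes form its signature, and the union of signatures is the
   next iteration's training set.

The loop stops when two consecutive clusterings agree exactly. Classes with
fewer than 5 cells are excluded, per-group class frequencies are tabulated
(excluded cells stay in the denominator), and each retained class's
signature is refined to its **unique genes**: expressed at log₂(TPM+1) > 2
in more than 50% of the class's cells and in at most 10% of every other
class's cells. Unique genes feed two downstream analyses: directed
receptor–ligand edges A→B wherever a curated (ligand, receptor) pair has
the ligand unique to A and the receptor unique to B, and a bulk-tissue
validation that counts, per class, the unique genes with detectable bulk
signal (mean TPM ≥ 1 in some group) and those significantly enriched in the
focal tissue (one-tailed pooled-variance Student's t on log₂(TPM+1),
p < 0.05 against every reference group).

## Worked example

The numbered scripts under `analysis/` run the whole study-shaped analysis
(17 planted subpopulations, 11 of them under the 5-cell exclusion
threshold) and write their tables under `results/`:

```
python analysis/01_simulate.py
python analysis/02_cluster.py
...
python analysis/06_validate_tissue.py
```

`02_cluster.py` prints:

```
converged after 3 iterations: True
terminal classes (clusters + subclusters): 17
major classes after <5-cell exclusion: 6 (11 excluded)
adjusted Rand index vs ground truth: 1.000

per-group class frequencies (%):
               ProB  cILC2  gdT  L-ILC2  BD-ILC1  BIM  Total %
PBS-Liver        76      0    7       0        0    0       83
Liver-1d-IL33    56      1   25       0        0    1       83
Liver-4d-IL33    18     53    3      16        0    0       90
EHBD-4d-IL33      3     56    3       0       16   11       89
```

— the pipeline finds the 17 planted subpopulations, retains 6 major classes
after excluding the 11 minor ones, and the frequency table shows the
planted tissue restriction: the Pro-B-like class dominates the PBS liver
(76%), the γδ-T-like class peaks at day 1 of IL-33 (25%), and the BIM- and
ILC1-like classes appear only in the bile duct. `06_validate_tissue.py`
then reports that all unique genes of the two duct-restricted classes are
significantly enriched in the duct bulk samples, while the liver-resident
classes' genes are not.

The same stages are available programmatically (`itersig.iterate`,
`itersig.class_signature`, `itersig.unique_genes`,
`itersig.predict_interactions`, `itersig.validation_report`) and as one
call, `itersig.run_all(config, out_dir)`, which writes every stage's tables
plus a reproducibility manifest.

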