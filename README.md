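# kifscore

Survival-directed gene-set scoring and downstream genomic association
analysis for pan-cancer-style cohorts.

## The problem

Gene families (the motivating case is the kinesin superfamily, *KIF* genes)
often act on tumor biology as a group rather than through any single member.
This package quantifies a family's overall activity per tumor sample in a
way that is *directed by survival*: family members that predict poor outcome
and members that predict good outcome are scored separately, and the gap
between the two is the sample's score.

The pipeline, for analysts working with expression + clinical + copy-number
+ mutation tables:

1. **Risk partition.** For each gene, in each cohort (cancer type), fit a
   univariate Cox proportional-hazards model of the survival endpoint on
   continuous expression. A gene with Wald p < 0.05 and hazard ratio
   HR > 1 is *high-risk* in that cohort; p < 0.05 with HR < 1 is *low-risk*.
   Genes whose high-risk cohort count strictly exceeds their low-risk count
   form the **positive set**; all other screened genes form the **negative
   set**.
2. **Set scoring.** A single-sample enrichment statistic (gene set
   variation analysis style) scores each set in each sample: per-gene
   Gaussian-kernel CDF estimates across samples (bandwidth sd/4), within-
   sample ranking, symmetric rank statistic r = |p/2 − rank|, and a
   weighted Kolmogorov–Smirnov-like random walk whose extreme deviations
   give the enrichment score ES ∈ [−1, 1]. The sample's score is
   **ES(positive) − ES(negative)**; samples split into high/low groups at
   the cohort median.
3. **Genomic burden.** Copy-number segments are binned
   ({−2,−1,0,1,2} at log2-ratio cutpoints −1, −0.25, 0.25, 1) and
   decomposed additively into focal, arm-level, and chromosome-level
   scores (both arms binning to the same nonzero value is one chromosome
   event); arms are called gain/loss at mean log2 ratio ±0.25. Tumor
   mutation burden is the nonsilent mutation count per megabase.
4. **Association suite.** Cox/Kaplan–Meier prognosis of the score on OS /
   DSS / DFI / PFI; covariate-adjusted (age, sex, race) linear models of
   burden and TMB on the score; Spearman panels against arbitrary
   per-sample feature tables (immune infiltration, stemness, HRD, ...) with
   Benjamini–Hochberg correction per panel; rank-sum / Kruskal–Wallis /
   Fisher / paired group tests; and a differential-expression filter
   (|log2FC| > 1, padj < 0.05).
5. **Consensus selection.** LASSO-logistic regression (CV-chosen penalty),
   random forest (above-mean impurity importance), and SVM-RFE (CV error
   minimum over surviving-set sizes) each select genes from a candidate
   panel; their intersection is the hub-gene list.

Because real pan-cancer archives are too large to ship, the package
includes a first-class synthetic-cohort generator
(`kifscore.synthetic_cohort`) that plants every effect the pipeline is
meant to detect — hazard-directional genes, focal/arm/chromosome
copy-number events, score–feature correlations — and records the ground
truth, so the whole chain is testable end to end.

## Worked example

```python
from kifscore import synthetic_cohort as sc, risk_partition as rp
from kifscore import setscore_engine as se, association_suite as assoc

spec = sc.CohortSpec(n_samples=200, n_cohorts=2, n_genes=30,
                     n_positive=5, n_negative=5, seed=42)
bundle = sc.generate_cohort(spec)

records = rp.screen_genes(bundle.expression, bundle.clinical, endpoint="OS")
positive, negative = rp.partition_genes(records)
print("positive set:", positive)

scores = se.compute_kifscore(
    bundle.expression, positive, negative,
    cohorts=bundle.clinical.set_index("sample")["cohort"])
print(scores.head(3).round(3).to_string(index=False))

prog = assoc.score_prognosis(scores, bundle.clinical, endpoint="OS",
                             per_cohort=False)
print("OS hazard ratio per unit score: %.2f (p = %.2e)"
      % (prog.loc[0, "hr"], prog.loc[0, "p"]))
```

Output:

```
positive set: ['G0000', 'G0001', 'G0002', 'G0003', 'G0004', 'G0023']
   sample  es_positive  es_negative  kifscore cohort group
C01-S0000       -0.115        0.167    -0.282    C01   low
C01-S0001        0.561       -0.428     0.989    C01  high
C01-S0002        0.103       -0.289     0.392    C01  high
OS hazard ratio per unit score: 2.09 (p = 1.56e-25)
```

The screen recovered the five planted hazard-increasing genes (G0000–G0004,
plus one false positive among the 20 null genes) into the positive set;
each sample's score is the difference of the two set activities, and a unit
increase of the score roughly doubles the hazard of death, recovering the
planted survival effect.

A thin CLI mirrors the stages:

```sh
kifscore simulate --out cohort/ --seed 7
kifscore partition --expr cohort/expression.tsv --clinical cohort/clinical.tsv --out partition.yaml
kifscore score --expr cohort/expression.tsv --partition partition.yaml \
    --clinical cohort/clinical.tsv --out scores.tsv
kifscore burden --seg cohort/segments.seg --arms cohort/arms.bed \
    --maf cohort/mutations.tsv --out burden.tsv
```

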