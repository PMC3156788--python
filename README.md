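# kinomet

Metagene-based prognostic signature discovery and validation for basal
breast cancer expression cohorts.

Basal breast cancers are high-grade, mostly hormone-receptor- and
ERBB2-negative tumors with poor but *heterogeneous* prognosis: standard
histoclinical factors and the common proliferation-driven expression
signatures fail to separate the patients who will relapse from those who
will not. One productive approach restricts attention to the kinome
(~660 kinase and kinase-interacting genes), summarizes coherent groups of
co-expressed genes into single "metagene" scores, and asks which metagene
predicts disease-free survival (DFS). In published work of this kind, the
winning metagene is an immune one — high expression of cytotoxic
T-cell-activation kinases (*LCK*, *ZAP70*, *SYK*, *ITK*, *JAK3*, ...) marks
a good-prognosis subgroup.

`kinomet` re-implements that discovery procedure as a tested, reusable
pipeline, together with a synthetic multi-series cohort generator so that
every stage can be exercised and validated without access to patient data.

## Method

Given a training cohort (log2 expression, genes × samples, plus censored
DFS), the pipeline:

1. **Preprocesses** — quantile normalization across samples, per-gene median
   centering, optional restriction to a kinome gene list
   (`kinomet.io`).
2. **Assigns molecular subtypes** by nearest centroid: each sample gets the
   subtype (basal / luminal A / luminal B / ERBB2 / normal-like) whose
   centroid it best correlates with (Pearson, shared genes); the basal
   subset is carried forward (`kinomet.subtyping`).
3. **Selects basal-upregulated genes** — per-gene Welch t-tests of basal vs
   each other subtype, Benjamini–Hochberg FDR within each comparison; a gene
   is kept if it is significantly up in basal (p < 0.05, FDR < 5%) in at
   least one comparison (`kinomet.discovery`).
4. **Clusters the selected genes** with quality-threshold (QT) clustering:
   grow a candidate cluster greedily from every seed gene, keep the largest
   whose minimum pairwise Pearson correlation stays ≥ 0.6, emit it if it has
   ≥ 15 members, remove its genes and repeat.
5. **Builds metagenes** — a cluster's score for a sample is the mean of its
   member genes' normalized expression — and **screens** each against DFS
   with univariate Cox regression (hazard ratio per unit score, Wald test).
6. **Dichotomizes** the prognostic metagene at the survival-optimal
   threshold τ: among all midpoints between consecutive distinct scores
   whose two groups each hold ≥ 10% of samples, take the one maximizing the
   log-rank statistic. Samples score > τ are "Metagene-High", the rest
   "Metagene-Low" (`kinomet.classification`).
7. **Validates across series** — the frozen τ is applied to each validation
   series after the same per-series gene median centering, series covering
   too few signature genes are excluded, subgroups are pooled, and 5-year
   DFS (Kaplan–Meier S(60 months)) is compared between High and Low.
8. **Assesses specificity** with a resampling null: B random gene sets of
   the same size are scored and Cox-screened; the tail probability is the
   fraction achieving a Wald p at least as good as the observed metagene
   (with a +1/(B+1) correction).

Supporting statistics (Kaplan–Meier with Greenwood variance, log-rank, Cox
with Efron ties and the univariate-p < 0.05 entry rule for multivariate
models, Fisher's exact test with cross-product or conditional-MLE odds
ratios, Welch's t) live in `kinomet.survstats`.

## Worked example

The package ships a generator that emulates the study design: five
molecular subtypes, a kinome-sized gene panel, two planted 28-gene
basal-upregulated clusters — one driving survival with a hazard ratio of
0.3 per metagene unit, one survival-neutral — and five independent series
with platform shifts and gene dropout.

```python
import kinomet as km

config = km.RunConfig(seed=7, resampling_B=2000)
result = km.run_pipeline(config, "out/")
print(result.screening.round(4))
```

The run log (`out/run_log.txt`) traces the stages:

```
stage=simulate n_series=5 n_samples=365 n_genes=629
stage=subtype n_basal=102 n_unclassified=4
stage=de n_selected=84
stage=qt n_clusters=2 sizes=26,25
stage=screen n_flagged=1
stage=cutpoint threshold=-0.0566062 chi2=34.18
stage=resampling B=2000 observed_p=8.14e-07 tail=0.0004998
stage=validate n_pooled=463 n_high=394 n_low=69 logrank_chi2=91.49 logrank_p=1.12e-21
```

Both planted clusters are recovered by QT clustering (26 and 25 of their 28
genes survive gene dropout and the correlation floor), but only the planted
prognostic metagene is flagged by the Cox screen:

```
                hr  ci_low  ci_high       p      n  flagged
metagene_1  1.0153  0.6732   1.5311  0.9422  102.0    False
metagene_2  0.2890  0.1764   0.4733  0.0000  102.0     True
```

The fitted hazard ratio 0.29 per metagene unit recovers the planted 0.3.
Applying the learned threshold to the four validation series and pooling
gives a 5-year DFS of High vs Low per series of 68/34, 78/26, 86/16 and
71/31 percent — a mean gap of 49.3 percentage points (95% CI 23.6–75.0) —
and only ~0.05% of 2000 random same-size gene sets match the observed
metagene's prognostic Wald p.

A command-line interface mirrors the stages
(`kinomet simulate | preprocess | subtype | discover | classify | validate
| report | run`); every tabular artifact is TSV and the classifier persists
as a small JSON document.

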