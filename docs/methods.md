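# Methods

This note documents the models, conventions and design choices behind
`kinomet`, in the order the pipeline uses them.

## Synthetic cohort model

The generator (`kinomet.simulate`) produces multi-series cohorts intended to
exercise every downstream stage under conditions resembling a
basal-breast-cancer kinome study: a training cohort of a few hundred early
tumors spread over five molecular subtypes, and several independent
validation series profiled on imperfectly matched platforms.

**Expression.** Values are drawn directly on the log2 scale (real inputs are
post-RMA/quantile-normalized, hence already log-like) with Gaussian per-gene
noise — the downstream t-tests and Pearson correlations assume approximate
normality, which is reasonable for normalized microarray intensities but
not for raw counts. A planted cluster of size *m* with target within-cluster
correlation *r* is generated from a shared latent factor:

    gene_i = f + eps_i,   f ~ N(0, sigma^2),  eps_i ~ N(0, sigma^2 (1-r)/r)

so the population pairwise Pearson correlation between members is exactly
*r*. Cluster genes additionally receive a constant `subtype_shift` (log2
units) in basal samples only, which is what makes them discoverable by the
basal-vs-rest supervised selection. Each of the five subtypes also gets its
own small block of independent marker genes (default 20 genes shifted by
+1); without them the four non-basal subtypes would be statistically
exchangeable and nearest-centroid assignment would scatter ~20% of them
into the basal group, which no real cohort shows.

**Survival.** Disease-free survival is exponential with hazard

    h(s) = baseline_hazard * exp(log_hazard_per_unit * (s - mean(s)))

where *s* is the *latent* prognostic score: the prognostic cluster's mean
expression with the basal detectability shift removed. Linking survival to
the shift-inclusive mean would make the whole basal subgroup a low-hazard
stratum (the shift moves every basal sample one unit up) and starve it of
events; with the latent link the basal subgroup keeps the designed event
rate, matching the cohorts being emulated (~35–40% events). Censoring is an
independent exponential plus an administrative cap — published cohorts
report only median follow-up, so a censoring *model* has to be assumed, and
independent exponential is the simplest one consistent with those medians.

**Platform effects.** Each series draws fresh samples, then a per-gene
additive shift (sd `series_shift_sd`) and a random gene subset removed with
probability `gene_dropout_prob`, emulating cross-platform transfer with
partial gene coverage. Per-gene median centering removes the additive
shifts exactly; dropout is handled by the metagene coverage rule.

**Defaults and why.**

| parameter | default | rationale |
|---|---|---|
| `n_samples_per_subtype` | 73 | the emulated training cohort contains 73 basal tumors |
| `n_genes` | 661 | kinome-list size after platform matching |
| planted clusters | 2 × 28 genes, r = 0.75, shift +1 | 28 is the discovered immune-cluster size; r = 0.75 makes the population minimum pairwise correlation clear the QT floor (0.6) by ≥ 2 sampling standard deviations at n ≈ 73, i.e. the planted block is a "robust cluster" in the QT sense by construction — at r = 0.7 the sample minimum over 378 pairs dips below the floor in ~10% of cohorts, contradicting the design being emulated |
| `log_hazard_per_unit` | log 0.3 | hazard ratio of the immune metagene scale reported for such signatures |
| `baseline_hazard` | 0.0077 /month | gives ~63% 5-year DFS, the training-cohort figure |
| `censor_rate` | 0.0108 /month | median censoring time ~64 months, the reported median follow-up |
| `max_followup` | 120 months | typical administrative horizon |
| `n_series` | 5 | one training + several validation series at desk scale (the emulated study pooled twelve) |
| `series_shift_sd`, `gene_dropout_prob` | 0.3, 0.05 | visible platform shifts; ~26–27 of 28 signature genes present per series, matching the reported ≥ 25/28 (mean 27) coverage |

Everything is driven by `numpy.random.default_rng` seeded from
`(seed, series_index, stage)`, so cohorts are fully reproducible and stages
can be re-run in isolation.

**What the generator does not emulate:** probe-level effects, intensity-
dependent (non-additive) batch effects, correlated censoring, competing
risks, non-proportional hazards, and any coupling between clinical
covariates and expression (covariates are independent Bernoulli fills).
Passing tests therefore demonstrate correctness of the *procedure* under a
faithful idealization, not robustness to every artifact of real microarray
compendia.

## Preprocessing conventions

* **Quantile normalization**: each sample's sorted values are replaced by
  the across-sample mean of order statistics; ties receive the mean of the
  reference values over their rank span. On tie-free data the operation is
  exactly idempotent; with ties a second application contracts tied groups
  further (the tie rule averages the reference, changing it) — a known and
  accepted property of the convention.
* **Probe collapse**: duplicate gene rows keep the row with the largest
  inter-quartile range (the most informative probe).
* **Median centering**: per gene, across samples; even counts subtract the
  mean of the two middle values.
* **Gene matching**: case-insensitive exact symbol match, no alias
  expansion — alias tables drift across annotation releases, and the gene
  lists involved supply plain symbols.
* **Missing values** are disallowed after ingestion; a gene missing in a
  series is treated as absent from that series' platform, which the
  signature coverage rule already handles.

## Subtype assignment

Nearest-centroid ("single sample predictor" style): Pearson correlation of
each sample against each subtype centroid over their shared genes, after
per-gene median centering; the label is the argmax. Samples whose best
correlation is negative, or whose margin over the runner-up is below
`min_margin` (default 0), are "unclassified". Correlation metric and the
unclassified rule are configurable because published SSP implementations
vary on both. Centroids are an input file — the published ones are
third-party artifacts — and on synthetic cohorts they are built as
per-subtype gene means.

## Supervised selection and QT clustering

Welch's t-test is used for the basal-vs-each-other-subtype comparisons
(groups are small and heteroscedastic), with Benjamini–Hochberg FDR applied
within each comparison; selection requires direction (up in basal), raw
p < α and adjusted p < the FDR threshold in at least one of the four
comparisons.

QT clustering uses the *diameter* quality criterion: a cluster is
admissible while its minimum pairwise Pearson correlation stays ≥
`min_corr` — the strictest reading of a "minimal correlation" floor. The
candidate for each seed is grown greedily, always adding the gene that
keeps quality highest; the largest candidate wins (ties: higher quality,
then lower seed index), is emitted if ≥ `min_size`, and its genes are
removed. A seed-correlation quality mode (`mode="seed"`) is available
behind a flag. On instances small enough to enumerate (≤ 12 genes) the
greedy procedure reproduces the exhaustive-search optimum on every
planted-block instance tested; ties between equal-size subsets at the
feasibility boundary are resolved by quality, where the greedy and the
enumeration can legitimately differ on degenerate near-ties.

## Metagenes and Cox screening

A metagene's score is the arithmetic mean of its member genes' normalized
expression per sample; per-series coverage (present/total members) is
recorded, and scoring fails loudly below the coverage floor (the pipeline
uses ⌈25/28 × size⌉, the published coverage rule expressed as a fraction so
it scales with the discovered signature size). Screening fits a univariate
Cox model per metagene on the continuous score (lifelines, Efron ties);
metagenes with Wald p < 0.05 are flagged.

The resampling null redraws `k`-gene sets without replacement from a pool
(default: all genes present in the matrix — whether the original analysis
drew from the kinome, the selected genes or the whole genome is not stated,
so the pool is configurable), scores each, and fits the same univariate
model. Because this requires ~1e5 Cox fits, the module uses a dedicated
single-covariate Newton solver (`survstats.UnivariateCox`) with Efron tie
handling, precomputing the risk-set bookkeeping once per dataset; it is
validated against lifelines and a grid-search partial-likelihood oracle to
1e-3. The tail probability uses the add-one correction (#{p ≤ obs}+1)/(B+1)
to avoid zero estimates. "At least as prognostic" is interpreted as Wald
p ≤ observed (the alternative |log HR| ordering is not used).

## Cutpoint optimization and transfer

Candidate thresholds are midpoints between consecutive distinct training
scores; a candidate is admissible if both induced groups hold ≥
`min_group_fraction` of samples (default 10% — optimal cut-point scans
otherwise drift to 1-vs-rest splits, and 10% still admits the ~1:2 to 1:3
splits such classifiers typically produce). "Greatest DFS difference" is
operationalized as the maximal log-rank chi-square; ties go to the smaller
High group. The learned τ is applied to validation series after per-series
gene median centering — an absolute threshold is meaningless across
platforms, and centering is the preprocessing profile under which a single
τ transfers; the profile is stored inside the persisted classifier JSON so
application cannot silently diverge from training. Optimism of the
optimized cut-point is quantified by the resampling machinery rather than
internal cross-validation (the design being emulated used external
validation).

Per-series validation reports 5-year DFS in both subgroups and their
difference, with an across-series t-based 95% CI on the mean difference;
series failing the coverage floor are excluded with a warning.

## Survival statistics conventions

* Kaplan–Meier: events precede censorings at tied times; Greenwood
  variance; 5-year DFS is S read at 60 months left-continuously.
* Log-rank: O−E chi-square, df = groups − 1 (lifelines).
* Cox: Efron tie handling throughout (the modern default; the emulated
  analyses do not state their choice). Multivariate models auto-enter
  covariates with univariate p < 0.05 and drop samples missing any
  *selected* covariate — complete cases on the entered variables only —
  with an audit trail of what qualified.
* Odds ratios: the sample cross-product (a·d)/(b·c) is the default
  estimate; the conditional-MLE estimate that R's `fisher.test` prints is
  available as `estimate="conditional"` (the two differ visibly only in
  small tables). Confidence intervals are Woolf logit by default, exact
  conditional on request; published CIs for such tables are typically the
  conditional ones, so CI method should be chosen to match the comparison
  target.

## Problem sizes used by the test suite and acceptance script

The suite exercises the pipeline at the design defaults (365-sample
cohorts, 661-gene panel, 5 series, 50 discovery replicates) and uses
B = 500–2000 for resampling nulls and 100-instance batches for the
brute-force oracle comparisons; the acceptance script runs the full
pipeline once at the defaults with B = 2000. These are the package's
chosen demonstration scales; the printed reference analysis used
B = 100,000 iterations, which `RunConfig` keeps as its default for real
runs.

## Known limitations

* The QT diameter criterion makes emitted cluster sizes shrink relative to
  the planted size at realistic sample counts (sample correlation jitter
  trims ~2–5 genes of 28); the seed-quality mode emits larger, looser
  clusters.
* The Cox screen's 5% level means a survival-neutral cluster is flagged in
  ~5% of cohorts; the resampling null, not the screen, is the specificity
  instrument.
* With four exchangeable non-basal subtypes and `min_margin=0`, subtype
  assignment of non-basal samples is only as good as the marker blocks; the
  basal subset inherits a few percent contamination, as real SSP calls do.
* The cutpoint scan maximizes an optimized statistic; its training-set
  chi-square is optimistically biased by construction and should never be
  quoted as evidence — only external-series performance counts.
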