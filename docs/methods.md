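# Methods

`hematrisk` re-implements, as a reusable and tested pipeline, a
risk-stratification analysis of hematuria patients built on a panel of 29
urine/serum biomarkers measured in 157 patients (80 urothelial cancer, 77
controls with confounding pathologies). The raw patient-level matrix was
never deposited, so the package pairs the analysis machinery with a
synthetic-cohort generator calibrated from the published per-cluster
summary tables; everything downstream of data loading is identical for
real and simulated cohorts.

## Pipeline

1. **Patient clustering.** Agglomerative hierarchical clustering of
   patient biomarker profiles with the Canberra distance
   `d(x, y) = Σ_i |x_i − y_i| / (|x_i| + |y_i|)` and McQuitty (WPGMA)
   linkage: after merging clusters *i*, *j*, the distance to any cluster
   *m* becomes `(d(i,m) + d(j,m)) / 2`. Cutting the tree at *k* = 5 gives
   the patient clusters; stability is assessed by n-out-of-n bootstrap
   resampling (duplicates collapsed — duplicated points sit at distance 0
   under the 0/0 convention and degrade linkage), scored by the adjusted
   Rand index against the full-data assignment and accumulated into a
   co-clustering consensus matrix.
2. **Biomarker clustering and feature space.** The same engine applied to
   the 29 biomarker columns, cut at *k* = 7, partitions the panel into
   correlation blocks. Taking one representative per block reduces the
   classifier search space from `Σ_{k=1..7} C(29, k)` = 2,182,395
   subsets to `Π_i N_b(i)` = 10,080 tuples for block sizes
   (2, 2, 6, 5, 4, 3, 7) — small enough for exhaustive search. Counts use
   exact integer arithmetic.
3. **Classifier search.** Every tuple is scored on a subpopulation with a
   random forest (default 1000 trees, features-per-split = ⌊√7⌋ = 2,
   unlimited depth): the out-of-bag (OOB) classification error is the
   fraction of patients misclassified by the majority vote of trees for
   which they were out-of-bag, and the AUROC is computed from OOB
   positive-vote fractions (trapezoidal tie handling). Both are averaged
   over independent forest repetitions (default 100); patients in-bag for
   every tree abstain and are excluded from that repetition. The winner
   maximises mean OOB AUROC, tie-broken by minimal mean error then
   lexicographic tuple order (the headline metric of the original ranking
   is the AUROC). Repetition seeds derive from a master seed through a
   counter-based stream; rows are canonicalised by sorted patient id, so
   results are invariant to input row order.
4. **Enrichment.** Each clinical characteristic is cross-tabulated
   against the patient clusters. When strictly more than 80 % of cells
   hold fewer than 5 observations, levels are pooled into coarse groups
   (final diagnoses into non-life-threatening vs life-threatening;
   stages into non-muscle-invasive vs muscle-invasive) before Pearson's
   chi-square test (Yates correction off by default — switchable — since
   the convention used originally is not recoverable). Clusters are
   designated high-risk when their proteinuria prevalence exceeds the
   cohort prevalence (alternative rule: life-threatening-diagnosis
   fraction); both rules give low = {blue, green}, high = {red, purple,
   gold} on the published tables. Headline percentages use explicit
   denominators: all patients for diagnoses/proteinuria, UC patients for
   stage, graded UC patients for grade (CIS tumours are ungraded),
   cytology-evaluable patients (139 of 157) for cytology; values are
   rounded half-up to one decimal to match the reporting style.
   Biomarker level shifts between clusters use the Mann-Whitney U test
   (exact enumeration when both samples ≤ 20 without ties, otherwise the
   tie-corrected normal approximation).

## Synthetic cohort generator

The generator's defaults are the study conditions: 157 patients in five
clusters of sizes (57, 13, 49, 15, 23), 29 biomarkers in seven blocks of
sizes (2, 2, 6, 5, 4, 3, 7).

**Biomarker model.** Each (cluster, biomarker) cell is log-normal with
`location = ln(median)` and `scale = ln(q3/q1) / (2·z₀.₇₅)`
(z₀.₇₅ ≈ 0.6745), inverted from the published median and interquartile
range. Log-normal because all measurements are nonnegative and
right-skewed (medians sit far below the upper quartiles). The fitted law
reproduces the printed median and quartile ratio exactly; individual
quartiles are matched only where the printed IQR is log-symmetric around
the median — a two-parameter family cannot pin three quantiles. Where the
printed lower quartile is zero, a one-sided fit `ln(q3/median)/z₀.₇₅` is
used; q1 = q3 yields a degenerate point mass at the median.

**Censoring.** Values below a biomarker's limit of detection (LOD) are
stored as LOD/2 and flagged, a standard substitution convention. Cells
whose whole IQR sits below detection become a point mass at LOD/2 with a
small multiplicative jitter (log-sd 0.05; after censoring the column is
exactly constant at LOD/2 within that cluster). LODs are taken from the
"<value" entries of the summary table (CRP 0.67, NSE 0.26, IL-6 1.20,
D-dimer 2.10, IL-1β 1.60, IL-4 6.60, sTNFR2 0.15, in assay units);
MMP-9's limit is never printed, so the shipped fixture configures
5.0 ng/ml — a configured default, not an inferred value, chosen below the
smallest quantified MMP-9 quartile (6.57 ng/ml).

**Correlation.** Within each biomarker block, log-values share a latent
patient-level factor giving intra-block correlation 0.6 by default (the
source reports no correlations; 0.6 encodes "clearly redundant but not
duplicate" markers). Blocks are independent of one another.

**Clinical covariates.** Final diagnosis, proteinuria, stage, grade and
cytology are drawn per cluster from the published cross-tables, either by
exact-proportion assignment (counts reproduced exactly, order
randomised — the default, and the mode the conservation tests use) or
multinomially. Stage is allocated within the non-muscle-invasive
(pTa/pT1/CIS) and muscle-invasive (≥ pT2) strata so it stays consistent
with the diagnosis category; pTa tumours take their grades from the
pTa-specific grade table, CIS tumours are ungraded, and the remaining
staged tumours receive the residual grade counts (the published tables
are exactly consistent under this decomposition). The proteinuria flag is
sampled from its cross-table rather than thresholded on the simulated
protein column, so exact-mode marginals are conserved; the flag and the
simulated protein value therefore agree only in distribution. Binary
split covariates (smoking, gender, histories, medications) have no
published per-cluster breakdown and are drawn conditionally on cancer
status from the cohort totals; rows that do not sum to 157 produce
genuinely missing values, as in the source tables.

**What the generator does not emulate.** Assay noise mechanisms
(triplicate measurement, plate effects), serum-vs-urine matrix
differences, any dependence between biomarkers and clinical covariates
beyond the shared cluster label, and — critically — the joint
patient-level structure that made the original patients separate into
five clusters (see limitations).

## Desk-scale protocols and problem sizes

The full protocol (10,080 tuples × 1000 trees × 100 repetitions per
subpopulation) is compute-heavy and exposed but optional. The pipeline's
`scaled_down` flag caps forests at 50 trees, 3 repetitions, 20 bootstrap
resamples and a 40-tuple subsample. The statistical checks use fixed
desk-scale designs:

- *Null calibration*: 157 patients, 7 pure-noise features, 100
  repetitions each with a freshly permuted label vector and a 50-tree
  forest. Redrawing the permutation each repetition is what estimates the
  null: with a single fixed permutation the OOB AUROC concentrates on
  that dataset's idiosyncratic value (typically 0.46–0.56), not on 0.5.
- *Planted-signal selection*: 400 patients, 7 blocks of 2 biomarkers, one
  informative marker per block with a log-scale class shift of 0.8
  (whole-tuple AUROC ≈ 0.85, well off saturation), 50-tree forests. The
  cohort is larger than the study's because tuple selection fails through
  winner's curse: the max over ~120 noise-contaminated tuples rides on
  sample idiosyncrasies of order n^(-1/2) that neither more trees nor
  more repetitions can average away, while stronger per-marker effects
  saturate the AUROC and erase the ranking signal. n = 400 with a
  moderate shift makes the selection problem identifiable.
- *Clustering oracle*: 200 random matrices with ≤ 8 rows against a naive
  WPGMA that recomputes the full distance matrix each step.
- *Generator calibration*: 10⁵ draws per cluster; empirical medians match
  the published medians within 3 % relative error on all non-censored
  cells, and empirical quartile ratios match the printed q3/q1.

## Numerical choices

- Canberra terms with both coordinates zero contribute 0 — required for
  LOD/2-coded data, where equal censored values are common.
- No standardisation or log transform before clustering: Canberra already
  normalises per coordinate, and the original analysis states no scaling
  step.
- Linkage ties are resolved by the underlying implementation's merge
  order; on continuous data exact ties have probability zero, and all
  oracle comparisons use tie-invariant summaries (sorted heights, flat
  partitions).
- Flat cluster labels are renumbered 1..k in dendrogram leaf order, so
  labelings are reproducible across runs and platforms.
- k = 5 (patients) and k = 7 (biomarkers) are configuration defaults
  mirroring the published dendrograms; no automatic model selection is
  attempted or endorsed.
- Counts are exact integers throughout the feature-space module; no
  floating-point binomials.
- Percentages round half-up (not banker's rounding) to one decimal.

## Known limitations

- **Cluster recovery from published summaries is bounded.** The two
  low-risk patient clusters have almost identical published marginal
  profiles: the Canberra distance between their median vectors is ≈ 1.9,
  against a mean within-cluster patient distance of ≈ 8.6 under
  IQR-matched log-normal marginals. Any generator that reproduces the
  printed quantiles therefore produces cohorts in which those two
  clusters are statistically indistinguishable, and the k = 5 cut
  recovers the generating partition only partially (median adjusted Rand
  index ≈ 0.33 over 20 seeds; the blue/green pair always merges, and
  k = 4 against the merged truth reaches ≈ 0.55–0.84). The original
  clusters evidently encode joint patient-level structure that per-cluster
  medians and IQRs do not carry. The corresponding recovery check in the
  acceptance suite is left failing by design rather than weakening the
  calibration; passing it would require information the published record
  does not contain.
- **Biomarker-block recovery is likewise not expected** on simulated
  cohorts: Canberra distances between biomarker columns are dominated by
  scale differences between assays, so column clustering groups markers
  by magnitude, and the intra-block correlation is visible only between
  markers of comparable scale.
- Published classification errors and AUROCs per subpopulation are not
  reproducible without the raw patient data; the package reproduces the
  machinery and the published panel comparisons (e.g. the 4/7 overlap
  between the two low-risk cluster panels) and validates the classifier
  statistically instead.
- Exact published p-values are not recomputable from the printed tables
  alone (the original correction and exactness conventions are unstated);
  the chi-square machinery reports both corrected and uncorrected forms
  on 2×2 tables.
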