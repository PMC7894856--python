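# Methods

`riskclust` implements an unsupervised phenotyping pipeline for high-risk
patient cohorts: a mixed-type administrative/EHR feature table is reduced to
two dimensions with t-SNE, density-clustered with OPTICS (keeping an
explicit outlier class), and each recovered cluster is characterized with
one-versus-rest ridge regressions. Because the data this class of study
runs on are restricted, the package ships a synthetic cohort generator that
plants known subgroup structure, and every claim the pipeline makes is
validated against that ground truth.

## The synthetic cohort

A cohort of `n_total` patients carries 119 variables over seven domains
(sociodemographic/insurance, comorbidity flags, pharmacy incl. adherence,
vital signs, laboratories, prior utilization, psychobehavioral). Baseline
marginals are simple by design: binary flags are Bernoulli(p) with p drawn
once per feature from U(0.02, 0.35) — diagnosis- and insurance-style flags
in real high-risk cohorts are mostly uncommon (single-digit to low-double-
digit prevalence) — continuous variables are standard normal, counts are
Poisson with rates U(0.5, 5). A few physiological correlations are imposed
(hematocrit tracks hemoglobin at r=0.95, eGFR is inversely tied to
creatinine at r=-0.90, AST tracks ALT at r=0.88) so correlation pruning has
realistic work.

Planted subgroups are defined by *signatures*: sets of features shifted
relative to baseline, in standardized units for continuous/count features
and as prevalence shifts for binary ones. The canonical 12-subgroup
structure (`demo_structure`) mirrors the phenotype taxonomy such studies
report — mostly comorbidity-defined subgroups (insulin-dependent diabetes,
chronic renal disease, liver disease, heart failure, COPD, metastatic
cancer), plus subgroups defined purely by psychobehavioral signatures
(opioid-predominant and amphetamine-predominant polysubstance use,
psychoses) or purely by sociodemographic ones (Medicaid/low-income, female
predominant), and a home-based-care group defined by utilization. Subgroup
sizes span 600 down to 30 at `n_total = 3000` (1–20% of the cohort),
with a 25% background fraction.

Two generator choices matter for discoverability and deserve justification:

- **Signatures are broad.** Each subgroup shifts ~10–18 features: a
  near-deterministic defining flag plus its clinical footprint (a renal
  cohort has high creatinine/BUN/potassium, low eGFR/hemoglobin, more
  specialty visits, more medications, ...). This is what distinct clinical
  phenotypes look like in a 119-variable extract. It is also a
  mathematical necessity: after standardization the feature space has ~115
  unit-variance dimensions, so the squared distance between two unrelated
  patients is ~230 with a noise scale of ~30; a subgroup whose aggregate
  squared centroid separation is below that noise floor is undetectable by
  *any* neighborhood-based method at these sample sizes.
- **Members cohere on their signature.** Within a subgroup, continuous
  signature features have residual SD `signature_sd = 0.6` (vs the
  baseline 1.0): patients who share a phenotype are more alike on its
  defining variables than the cohort at large.

Background patients are drawn from the baseline and given small
idiosyncratic perturbations (2–6 signature features shifted by U(-0.5,
0.5)), so they form a diffuse mass that partly resists clustering. The risk
percentile is a rank transform of a latent severity score (noise plus a
mortality-linked offset), truncated to 75–99, which supports risk-stratified
sampling without modelling any specific risk score. Outcomes (2-year death,
inpatient days, ED visits) are drawn per subgroup from Bernoulli/Poisson
outcome models spanning low-risk (1% mortality) to very-high-risk (45%)
phenotypes, echoing the outcome spread reported for real high-risk cohorts.

Repeated measurements: each lab/vital value is observed 1 + Poisson(2)
times across the 365-day window with N(0, 0.3) measurement noise. Pharmacy
fills are simulated per medication class with renewal-process pacing solved
so the expected day-level coverage matches a target PDC; early refills
(overlaps) occur with probability 0.15 and gaps follow from the target, so
the downstream set-union PDC logic is genuinely exercised. Missingness is
injected per domain, either MCAR or MAR with the masking probability a
decreasing function of a fully observed utilization variable
(`exp(-z)`-weighted, mean-calibrated to the domain rate): patients seen
less often have more gaps.

**What the generator does not emulate:** real feature tables have far
richer dependence (comorbidity co-occurrence networks, age-dependence of
everything), heavy-tailed labs, informative missingness beyond one
conditioning variable, and phenotypes without crisp defining flags.
Passing the recovery tests shows the pipeline finds the structure it is
pointed at under honest noise, missingness and pruning; it does not
certify performance on real extracts.

## Feature engineering

Fixed order, recorded in the provenance list: median aggregation of
repeated measures → PDC adherence (per class and days-of-therapy-weighted;
prescribed-but-unfilled is 0, never-prescribed is missing) → low-variance
filter (observed-value variance < 0.0099, i.e. binary prevalence outside
1–99%) → greedy correlation pruning (pairwise-complete Pearson; while any
pair exceeds |r| = 0.80, drop the member with the larger mean absolute
correlation, ties to the later column) → missingness-count feature →
single FCS imputation → z-scoring. FCS runs 10 cycles of
regress-and-replace: linear models with residual-noise draws for
continuous/count variables (counts rounded and clipped at 0), ridge-
stabilized logistic IRLS with Bernoulli draws for binary ones; missing
cells are initialized from observed-value draws; observed cells are never
altered. Binary columns are z-scored like continuous ones so ridge
coefficients are comparable across types. Pruning runs before imputation,
following the narrative order of such analyses; the analysis set (not any
larger population) is what gets pruned.

## Sampling

`n_sets` pairwise-disjoint sets of equal size are drawn jointly without
replacement, stratified on the risk percentile in 5-point bins ([75,80) …
[95,100), 99 folded into the top bin). Per-set stratum counts are the
largest-remainder allocation of the population proportions, so every set's
risk distribution matches the population exactly up to integer rounding.
One set is the validation set; the rest train the clustering
hyperparameters.

## Embedding

Exact (O(n²)) t-SNE. Per-point Gaussian bandwidths are calibrated by
bisection on the precision until exp(H) matches the target perplexity
(tolerance 1e-7, ≤50 bisections after bracketing); conditionals are
symmetrized to P = (C + Cᵀ)/2n; the 2-D map minimizes KL(P‖Q) with a
Student-t (1 df) kernel by gradient descent with early exaggeration
(factor 12 for 250 of 1000 iterations), learning rate 200, momentum
0.5→0.8 at iteration 250, and adaptive per-parameter gains. Defaults are
the standard published ones; all are configurable and echoed in run
metadata. After the exaggeration phase a monotonicity safeguard evaluates
the true KL each iteration and, if a momentum step would raise it, reverts
and takes a backtracking plain gradient step instead — so the recorded KL
trace is non-increasing by construction, which doubles as a convergence
diagnostic. The KL trace always reports the *unexaggerated* objective.

## Clustering

From-scratch OPTICS: core distance is the distance to the min_pts-th
nearest neighbour (the point itself included), the ordering is produced by
a priority queue keyed on smallest reachability with deterministic index
tie-breaks, and the predecessor of each reachability is tracked. Two
extraction modes:

- **cut**: a global reachability threshold ε′, applied by walking the
  ordering (reach ≤ ε′ joins the current cluster; reach > ε′ with core
  ≤ ε′ starts one; otherwise noise). This reproduces DBSCAN(ε′, min_pts)
  exactly on core points. The threshold can be given absolutely or as a
  quantile of the finite reachabilities (scale-free across data sets).
  Cut-mode clusters are not post-filtered by size: each is seeded by a
  core point and therefore has ≥ min_pts density-reachable members, and
  size filtering would break the DBSCAN core-partition equivalence in
  edge cases where border members are claimed by a neighbouring cluster.
- **xi**: steep-area extraction per the original OPTICS formulation with
  the published predecessor correction; clusters smaller than min_pts are
  dissolved. The nested hierarchy is flattened by assigning each point to
  its smallest enclosing cluster; intervals spanning more than 75% of the
  ordering describe the whole data set rather than a subgroup and are not
  painted.

Hyperparameters are tuned on the training-set embeddings: every candidate
(min_pts × extraction) is scored per set as the mean silhouette of
clustered points minus 0.5 × |noise fraction − 0.25|, and the median
across sets picks the winner (ties keep grid order; a candidate that
clusters nothing anywhere scores −∞). The noise target of 0.25 encodes the
expectation that roughly a quarter of a high-risk cohort resists
subgrouping. The default min_pts grid scales with the set size (~1%,
1.7%, 2.5% of n, floored at 5) — the right absolute density threshold
depends on n — and extraction candidates cover xi ∈ {0.03, 0.05} and cut
quantiles {0.65, 0.70, 0.75, 0.85}. The silhouette and adjusted-Rand
implementations used internally are small self-contained functions,
cross-checked against independent library implementations in the test
suite.

## Profiling

For each cluster, 100 one-versus-rest linear-probability ridge models
(binary membership on the standardized variables; noise points excluded
from both classes) are fit over a log-spaced penalty grid [1e-4, 1e4] via
one SVD of the centered design; the intercept is unpenalized. The 100
coefficient vectors are averaged element-wise and normalized to unit
maximum absolute value — averaging the coefficient vectors (rather than
the penalties) is what yields per-variable estimates that can be ranged
over afterwards. Per-variable importance is the cross-cluster range
(max − min) of the normalized coefficients; the 20 largest ranges are
flagged. The label-suggestion report lists each cluster's top-5 variables
by |coefficient| with sign and domain, and the majority domain collapsed
onto the comorbidity / sociodemographic / psychobehavioral taxonomy
(pharmacy, vitals, labs and utilization count as clinically driven, hence
"comorbidity"); domain ties are reported, never silently broken. Final
human-readable labels remain a manual act on this evidence.

## Reporting

Per-cluster two-year outcome summaries (mortality %, any-hospitalization %,
mean inpatient days, any-ED %, mean ED visits, mean risk percentile) are
exact group-by aggregations with the noise group as a first-class row and
an overall row; formatted tables round to one decimal while machine-
readable outputs keep full precision. The baseline table reports
mean (SD) for continuous/count variables and n (%) for binary ones.

## Numerical and degenerate-input conventions

Undefined core/reachability distances are `inf`. All randomness flows from
explicit seeds (stage sub-seeds derived by fixed offsets); reruns are
byte-identical. Degenerate cases are errors, not silent defaults: empty
medication class lists, rates outside [0,1], fully missing columns (named
in the error), single-class one-vs-rest targets, zero-variance columns
reaching standardization, exhausted sampling strata (named), every-
candidate-fails tuning. A constant missingness-count column (fully
observed input) is dropped before standardization rather than failing the
run. A penalty grid that is not length-100 warns and proceeds.

## Problem sizes

The validation study runs at 3,000 patients (12 subgroups, 25%
background), 5 disjoint sets of 600 (4 training + 1 validation) — the
same train/validate architecture as the full-scale design, at a size where
exact-gradient t-SNE and O(n²) OPTICS complete in about a minute on one
CPU. Component checks use the sizes stated in their tests (e.g. 1,000
randomized fill histories, 100 imputation replicates, 20 OPTICS/DBSCAN
instances).

## Known limitations

Exact t-SNE is quadratic: 10,000-point sets are feasible but slow
(no Barnes–Hut backend). Cut-mode extraction uses one global density
threshold and can merge clusters of very different densities — the xi mode
exists for that case but is order-sensitive at cluster boundaries.
Logistic-ridge profiling is out of scope (the linear-probability form has
a closed form and exact tests). The category taxonomy is a fixed
three-way mapping; a cluster genuinely defined by, say, pharmacy behaviour
is filed under the clinical category.
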