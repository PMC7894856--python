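# riskclust

Unsupervised subgrouping of high-risk patient cohorts from mixed
administrative/EHR feature tables.

Patients flagged as high-risk by prediction models (e.g. a risk percentile
≥ 75 for one-year hospitalization or death) are a heterogeneous group:
some are driven by chronic disease, others by psychobehavioral or
sociodemographic circumstances, and one-size-fits-all care management
programs serve them poorly. `riskclust` implements the machine-learning
procedure used to discover such subgroups from a ~119-variable feature
table spanning sociodemographics/insurance, comorbidity flags, pharmacy
(incl. medication adherence), vital signs, laboratories, prior utilization
and psychobehavioral factors:

1. **Feature engineering** — median aggregation of repeated labs/vitals,
   proportion-of-days-covered (PDC) adherence from pharmacy fills,
   low-variance and |r| > 0.80 correlation pruning, a missingness-count
   feature, a single fully-conditional-specification (chained-equations)
   imputation, and z-scoring.
2. **Risk-stratified sampling** — disjoint training and validation sets
   drawn without replacement, stratified on the risk percentile in 5-point
   bins (largest-remainder allocation, exact set sizes).
3. **Embedding** — from-scratch exact t-SNE to two dimensions per set
   (perplexity-calibrated Gaussian bandwidths; KL(P‖Q) minimized with a
   Student-t kernel, early exaggeration and momentum; the post-
   exaggeration KL trace is non-increasing by construction).
4. **Density clustering** — from-scratch OPTICS with a reserved noise
   label; flat clusters extracted either by a reachability cut (exactly
   DBSCAN's core-point partition) or xi-steep areas; (min_pts, extraction)
   tuned on the training sets by a silhouette-with-noise-penalty score.
   Patients in no cluster stay an explicit outlier class — they are never
   forced into a subgroup.
5. **Profiling** — each cluster characterized by one-versus-rest ridge
   regressions over a 100-value penalty grid; coefficient vectors are
   averaged and max-abs-normalized, per-variable importance is the
   cross-cluster coefficient range (top-20 flagged), and an automated
   report suggests each cluster's label evidence and category
   (comorbidity / sociodemographic / psychobehavioral).
6. **Reporting** — per-cluster two-year outcomes (mortality,
   hospitalization and ED rates/counts) with the outlier group as a
   first-class row, plus a cohort baseline table.

Because the real data for such studies are restricted, the package
includes a first-class synthetic cohort generator (`riskclust.synthgen`)
that plants known subgroup signatures, repeated measurements, pharmacy
fill histories, missingness and outcome models — so the whole pipeline is
testable end-to-end against ground truth. See `docs/methods.md` for the
model details and design rationale.

## Worked example

```python
from riskclust import PipelineConfig, run_pipeline, adjusted_rand_index, NOISE

config = PipelineConfig(
    seed=7, n_total=1500, n_subgroups=8, n_sets=5,
    tsne_iterations=500, exaggeration_duration=125, momentum_switch=125,
)
result = run_pipeline(config)

labels = result.labels.to_numpy()
truth = result.true_labels.to_numpy()
clustered = labels != NOISE
print(f"tuned OPTICS config : {result.tuned_config.describe()}")
print(f"clusters found      : {len(result.profiles)}")
print(f"unclustered fraction: {(~clustered).mean():.3f}")
print(f"ARI vs planted truth: {adjusted_rand_index(truth[clustered], labels[clustered]):.3f}")
```

prints (about two minutes on one CPU):

```
tuned OPTICS config : min_pts=8, cut_quantile=0.7
clusters found      : 12
unclustered fraction: 0.263
ARI vs planted truth: 0.868
```

The tuner settled on a reachability cut at the 70th percentile with
min_pts = 8; 12 clusters cover ~74% of the 300-patient validation set and
agree with the planted subgroups at ARI 0.868, with the remaining quarter
left as outliers rather than forced into a cluster. The label-evidence
report makes the clusters interpretable — the largest ones read directly
as the planted phenotypes:

```
cluster 11 (n=45, comorbidity): -egfr, +hemoglobin_a1c, +insulin_use, +n_primary_care_visits, -creatinine
cluster 9  (n=30, comorbidity): -hemoglobin, +bun, +deficiency_anemia, -egfr, +hematocrit
cluster 10 (n=24, comorbidity): -albumin, +alt, -platelet_count, +alkaline_phosphatase, +coagulopathy
```

(insulin-dependent diabetes, chronic renal disease and chronic liver
disease respectively), and `result.outcome_summary` gives the per-cluster
outcome table, e.g. cluster 8 here carries 33.3% two-year mortality and
11.0 mean inpatient days against a cohort-wide 12.0% and 5.0.

The same pipeline is available stage-by-stage from the shell:

```bash
riskclust --config config.yaml --outdir out synth
riskclust --config config.yaml --outdir out features
riskclust --config config.yaml --outdir out sample
riskclust --config config.yaml --outdir out embed
riskclust --config config.yaml --outdir out tune
riskclust --config config.yaml --outdir out cluster
riskclust --config config.yaml --outdir out profile
riskclust --config config.yaml --outdir out report
# or everything at once:
riskclust --config config.yaml --outdir out run-all
```

where `config.yaml` is a flat key/value file (`seed` is required; every
tunable parameter of every stage is a key and is echoed into
`out/manifest.json`).

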