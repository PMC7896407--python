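# petsubtype

Data-driven subtyping of Alzheimer's-disease-related neurodegeneration from
FDG-PET hypometabolism patterns — as a fully synthetic, end-to-end testable
pipeline.

FDG-PET measures regional cerebral glucose metabolism; reduced uptake
(hypometabolism) is a sensitive marker of neurodegeneration. In AD-dementia
cohorts, hypometabolism is not spatially uniform: distinct regional patterns
("subtypes") exist — a *typical* posterior temporo-parietal pattern, a
*limbic-predominant* pattern centred on the medial temporal lobe with frontal
extension, and a rarer *cortical-predominant* pattern with widespread cortical
involvement but spared medial temporal lobe. These subtypes can already be
detected at the prodromal stage (amyloid-positive mild cognitive impairment)
and predict different clinical trajectories.

`petsubtype` is for methodologists who want to study, stress-test or extend
this analysis chain without access-controlled patient data. It provides:

1. **`petsubtype.simulate` / `petsubtype.atlas`** — a synthetic cohort
   generator: a toy label atlas (48 "cortical" parcels plus medial-temporal,
   frontal, posterior temporo-parietal sets and a pons reference region), 3-D
   images built from planted subtype templates under a multiplicative
   generative model, baseline covariates/biomarkers drawn from published
   cohort tables, and longitudinal cognition/CDR under proportional hazards.
2. **`petsubtype.preprocess`** — Gaussian smoothing (8 mm FWHM), global-mean
   and pons-reference intensity scaling, grey-matter masking, regional means
   and regional ratios.
3. **`petsubtype.cluster`** — Ward agglomerative clustering of globally
   scaled voxel profiles (statsmodels-style `SubtypeClustering(...).fit()` →
   results object), with objective cluster-number selection by the silhouette
   (primary) and Davies-Bouldin (secondary) criteria. Ward merge cost is
   ΔSSE = n_A·n_B/(n_A+n_B)·‖c_A − c_B‖²; dendrogram heights √(2·ΔSSE) are
   available for cross-checking against other implementations.
4. **`petsubtype.contrasts`** — voxel-wise two-sample GLM contrasts with
   age/gender/education covariates, converted to Cohen's *d* via
   d = t·√(1/n₁ + 1/n₂).
5. **`petsubtype.classify`** — the two-stage prodromal classifier: a subject
   passes the hypometabolism screen if any screened region's pons-scaled mean
   lies ≥ 1 SD below the control mean (otherwise "no hypometabolism"), and
   screen-passers are assigned to the nearest dementia-derived subtype
   centroid in Euclidean distance on globally scaled profiles.
6. **`petsubtype.outcomes`** — A/T/N biomarker classification (thresholds
   1.11 SUVR, 880/19.2/242 pg/ml), composite-score arithmetic, ANOVA/ANCOVA
   with BH-FDR post hocs, chi-square tests, progression events
   (CDR 0.5 → ≥ 1), Kaplan-Meier, Cox proportional hazards (Breslow ties),
   and linear mixed models of domain-specific cognitive decline.

## Worked example

```python
import petsubtype as pst
from petsubtype.simulate import CohortConfig, generate_cross_sectional, generate_longitudinal
from petsubtype.pipeline import run_pipeline_arrays
from petsubtype.outcomes import progression_table, cox_ph

atlas = pst.generate_atlas()
templates = pst.default_templates(atlas)
config = CohortConfig(seed=1)                      # 179 CN / 177 AD / 217 MCI
data = generate_cross_sectional(atlas, templates, config)
visits, _ = generate_longitudinal(data.cohort, config)

result = run_pipeline_arrays(data.images, data.cohort, atlas, templates)
print(result.clustering.summary())
```

```
Ward hierarchical subtyping
===========================
subjects: 177    voxels: 4032
selected k (silhouette): 3    Davies-Bouldin choice: 3
reported solution: k = 3

cluster sizes:
  cluster 1: n = 86 (48.6%)
  cluster 2: n = 79 (44.6%)
  cluster 3: n = 12 (6.8%)
```

Both validity criteria select three clusters, and the cluster sizes reproduce
the planted mixture (48.6% typical, 44.6% limbic-predominant, 6.8%
cortical-predominant). Classifying the simulated prodromal cohort and fitting
the progression model:

```python
print((100 * result.assignments["subtype"].value_counts(normalize=True)).round(1))

cohort = data.cohort.merge(result.assignments[["subject_id", "subtype"]],
                           on="subject_id", how="left")
records = progression_table(visits, cohort)
records = records[records["subtype"] != "cortical_predominant"]  # n = 3
print(cox_ph(records).summary[["term", "hr", "p"]].round(3))
```

```
limbic_predominant      53.5
no_hypometabolism       23.0
typical                 22.1
cortical_predominant     1.4

                       term     hr      p
subtype[limbic_predominant]  4.549  0.001
           subtype[typical]  7.306  0.000
                        age  0.994  0.740
```

23% of prodromal subjects show no regional hypometabolism (planted fraction
26.3%), roughly half are limbic-predominant, and subjects **with**
hypometabolism progress to dementia at ~5–7× the hazard of the
no-hypometabolism group (planted hazard ratios 4.82 and 5.99; at n = 217 the
estimates are noisy — the acceptance script recovers them at n = 2000 per
group to within a few percent).

A thin CLI wraps the same pipeline:

```bash
petsubtype simulate --seed 1 --out cohort/
petsubtype cluster  --cohort cohort/ --out clusters/
petsubtype classify --cohort cohort/ --out assignments.csv
petsubtype outcomes --cohort cohort/ --domain EF --out outcomes.json
```

## Layout

```
src/petsubtype/
  atlas.py        synthetic label atlas (parcels, sets, pons, gm mask)
  simulate.py     cohort generator: images, baseline tables, visits, events
  preprocess.py   smoothing, global/pons scaling, regional summaries
  cluster.py      Ward linkage, validity criteria, SubtypeClustering model
  contrasts.py    voxel-wise GLM t maps and Cohen's d conversion
  classify.py     hypometabolism screen + nearest-centroid assignment
  outcomes.py     baseline stats, survival and mixed-effects modelling
  pipeline.py     end-to-end orchestration
  cli.py          click-based command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
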