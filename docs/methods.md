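# Methods

This note documents the models implemented in `petsubtype`, the simulator
that exercises them, the parameter choices that matter, and what the
passing test-suite does and does not establish.

## The analysis chain

**Subtype discovery.** Dementia-group FDG-PET profiles (grey-matter voxels
of smoothed images) are divided by their own in-mask mean ("global
scaling") so that clustering responds to the *shape* of the regional
pattern, not to overall severity: global scaling is exactly invariant to
any per-subject positive intensity rescaling, a property the test-suite
asserts. Profiles are clustered by agglomerative Ward linkage. The merge
cost is stored as the increase in total within-cluster sum of squares,

    dSSE(A, B) = n_A n_B / (n_A + n_B) * ||c_A - c_B||^2,

updated with the Lance–Williams recurrence; ties are broken by the
lexicographically smallest node-id pair, making trees deterministic. Some
widely used implementations report dendrogram heights as sqrt(2*dSSE); the
mapping is strictly monotone, so topology and cuts are unaffected
(`cost_to_height` converts, and the tests verify height-equality against
an independent implementation). Two conservation/ordering facts pin the
convention: merge costs are non-decreasing (Ward is reducible — asserted
on every tree) and they sum to the total SSE about the grand centroid.

**Choosing k.** Dendrogram cuts for k = 2..10 are scored with the mean
silhouette coefficient (higher better; singletons and all-zero-distance
cases score 0 by Rousseeuw's conventions) and the Davies-Bouldin index
(lower better). The silhouette choice is primary; a disagreement between
the criteria is *reported* (warning plus both values in the results
object), never silently resolved — on realistic noise levels the
Davies-Bouldin index does occasionally favour 4 or 5 clusters while the
silhouette favours 3, and the pipeline then proceeds with 3.

**Effect-size maps.** Pons-scaled profiles (division by the mean signal of
a reference region spared by the disease) are compared voxel-wise between
groups by least squares with an intercept, a group indicator and
age/gender/education covariates; the group-column t statistic is converted
to Cohen's d by the standard two-sample formula d = t*sqrt(1/n1 + 1/n2).
Negative d means the first group is hypometabolic relative to the second.
The maps are descriptive; no voxel-wise multiplicity correction is applied
by default (a BH option exists in `outcomes.fdr_bh`).

**Prodromal classification.** Stage 1 screens pons-scaled regional means
against the control group: a region is flagged when its value is at least
one control SD below the control mean (inclusive at the boundary — fixed
so threshold tests are exact); subjects with no flagged region form the
"no hypometabolism" class. Stage 2 assigns each screen-passer to the
dementia-derived subtype whose mean globally scaled profile is nearest in
Euclidean distance over all grey-matter voxels; exact ties fall to the
model's fixed subtype order and are logged. The screen's default region
set is *all* grey-matter parcels: the 48-area cortical screen it emulates
covers frontal, temporal and parietal cortex, which in this package's toy
atlas is split across four named sets.

**Outcomes.** Progression is the first visit at which CDR reaches 1 or
more, for subjects entering at CDR 0.5; non-progressors are censored at
their last visit (event timing is carried on the visit grid, reflecting
visit-based CDR assessment). Kaplan-Meier curves use the product-limit
estimator (lifelines). Cox proportional-hazards fits use the Breslow tie
convention by default (Efron behind a flag) with subtype as a factor
against the no-hypometabolism reference and age/gender/education as
covariates; a four-subject partial-likelihood oracle in the tests pins the
estimator to 1e-6. Mixed models of domain scores include time, subtype,
subtype×time and covariates as fixed effects, with per-subject random
intercepts and slopes; when the random-effects covariance is singular the
model falls back to a random intercept with a warning. Inference on fixed
effects uses Wald z tests (the large-sample normal approximation); no
small-sample degrees-of-freedom correction is implemented, which is
adequate at the cohort sizes simulated here (hundreds of subjects) but
would be anticonservative for very small groups.

## The synthetic cohort generator

The generator exists so every downstream stage is testable with planted
ground truth. Subject *i* with subtype template delta(r) gets the
unsmoothed image

    image_i(x) = g_i * base(r(x)) * (1 - min(s_i * delta(r(x)), 0.6)) * q_i^[x in pons] + eps(x)

* `base` — 1.3 in grey matter, 1.0 in pons (cortex-to-pons uptake ratio of
  a healthy subject).
* `g_i ~ logNormal(0, 0.15)` — global uptake (scanner/dose/physiology); a
  pure nuisance removed exactly by global scaling.
* `s_i ~ Gamma(shape 4, mean 1.6 (dementia) / 1.2 (prodromal))` — severity
  multiplying the template's fractional reductions; the overlapping
  distributions mean some prodromal subjects are as affected as mild
  dementia cases. `severity_fixed` freezes s at the group mean for
  deterministic-limit tests.
* the reduction saturates at 60%: even end-stage disease does not abolish
  regional glucose metabolism, and the cap keeps the Gamma tail from
  producing non-physical negative uptake.
* `q_i ~ logNormal(0, 0.08)` — biological/technical variability of the
  pons reference signal, applied to pons voxels only. This is the dominant
  variance component of pons-scaled data: it makes a subject's regional
  z-scores strongly correlated, which is what real SUVR data look like and
  what gives the 1-SD screen its specificity. Without it (~50+ nearly
  independent regional z-scores per subject) essentially every null
  subject would flag at least one region and a planted ~26% "no
  hypometabolism" fraction could never be recovered.
* `eps ~ Normal(0, 0.08)` i.i.d. on labelled voxels.

With all three noise scales at 0 and severity fixed, the equation is
exactly invertible (delta recovered from the image and the manifest of
drawn parameters), which the tests use to pin the implementation.

**Atlas.** A deterministic partition of an ellipsoid on a 24×28×24 grid of
4 mm voxels: 48 generic cortical parcels plus 6 medial-temporal, 10
frontal and 12 posterior temporo-parietal parcels (~53 voxels each), and a
2×2×2 pons block below the ellipsoid, disjoint from the grey-matter mask.
Parcel geometry is nominal — compact chunks ordered along the
anterior-posterior axis — not anatomy.

**Templates.** Fractional reductions per region set
(mt / frontal / posterior-tp / anterior-cortical / posterior-cortical):

| subtype | mt | frontal | post-tp | cort-ant | cort-post |
|---|---|---|---|---|---|
| typical | 0.10 | 0 | 0.30 | 0 | 0.14 |
| limbic-predominant | 0.34 | 0.12 | 0.02 | 0.10 | 0 |
| cortical-predominant | 0 | 0.47 | 0.18 | 0.47 | 0.50 |
| no-hypometabolism | 0 | 0 | 0 | 0 | 0 |

The values encode the qualitative descriptions of the three patterns
(posterior temporo-parietal with milder medial-temporal involvement;
medial-temporal-predominant with frontal/anterior extension; widespread
cortical with spared medial temporal lobe, the most severe pattern) while
giving the three globally-scaled patterns near-equal norms and pairwise
negative correlations. That geometry is a deliberate design choice: under
the Gamma severity model each planted cluster is elongated along its own
pattern direction, and well-separated directions are what make the
three-cluster structure recoverable at the planted 44.6/48.6/6.8% mixture
with only 12 subjects in the smallest cluster. Real within-subtype
heterogeneity (template variability across patients) is *not* modelled;
recovery rates on this simulator are therefore upper bounds on what any
method would achieve on real data.

**Baseline tables.** Age, gender, education, MMSE, the four cognitive
composites, APOE ε4, amyloid-PET SUVR, CSF markers, volumetrics and WMH
are drawn per group/subtype from normal distributions (Bernoulli for
binary) with means/SDs set to the published cohort tables this simulator
emulates; the prodromal cortical-predominant cell (n = 3 in the source
cohort, never tabulated) is an invented plausible interpolation. Composites
are drawn independently of image severity — group contrasts are planted,
subject-level image-cognition coupling is not. The memory-minus-executive
difference is computed per subject, exactly, from the drawn MEM and EF.
The hippocampus-to-cortex volume ratio is reported as 1000·hv/ctv and
summarized as the mean of per-subject ratios (the ratio of group means
does not reproduce the emulated tables' magnitudes).

**Longitudinal model.** Visits every 6 months; each subject's last visit is
drawn uniformly from the 12–72-month grid (mean ≈ 42 months).
Domain scores follow `baseline + slope(subtype, domain)*month + u0 + u1*month + eps`
with u0 ~ N(0, 0.4), u1 ~ N(0, 0.005/month), eps ~ N(0, 0.25). Default
slopes order the subtypes as the emulated findings do: the
no-hypometabolism class declines minimally; typical declines fastest in
executive function; limbic-predominant and typical decline equally in
memory. Progression times are Weibull (shape 1 = exponential by default)
with baseline hazard 0.004/month for the no-hypometabolism reference —
chosen to give roughly 40–50% progression over follow-up — and hazard
ratios 4.82 (limbic-predominant) and 5.99 (typical); the
cortical-predominant cell, unreported in the source, reuses 5.99.

## Numerical conventions

* Smoothing: separable Gaussian, sigma = FWHM/(2·sqrt(2 ln 2)), kernel
  truncated at 4 sigma, zero padding — smoothed fixtures are
  bit-reproducible.
* Ward ties: smallest (min-id, max-id) pair; cut labels renumbered by
  decreasing cluster size (ties: smallest member id).
* Screen boundary inclusive (value ≤ mean − 1·SD flags); A-positivity
  inclusive at SUVR 1.11; the three CSF thresholds strict — boundary
  behaviour is pinned by tests.
* Pairwise post hoc tests run only when the omnibus p < 0.05, and are
  plain two-sample t tests (or 2×2 chi-square without continuity
  correction) with Benjamini-Hochberg adjustment.
* Largest-remainder rounding for planted subtype counts, so count-based
  checks are exact (177 × (0.446, 0.486, 0.068) → 79/86/12).
* Missing values in group tests: listwise deletion with dropped counts
  reported on the result object.

## Problem sizes

The test-suite and acceptance script run the full pipeline on cohorts of
the emulated study's actual size (179/177/217 subjects, ~4000 grey-matter
voxels), with 100 replicate cohorts for the stochastic recovery rates in
the tests and 20 in the acceptance script, and n = 2000 per subtype for
hazard-ratio recovery. These sizes give sampling error well below the
asserted tolerances while keeping a full run in minutes.

## Known limitations

* No within-subtype template heterogeneity, no spatial autocorrelation of
  noise, no partial-volume or scanner-harmonization effects; parcels are
  geometric chunks, not anatomy. Passing recovery tests demonstrates the
  correctness of the pipeline's machinery, not expected performance on
  real images.
* Cognitive/biomarker draws are independent across variables given the
  subtype, so multivariate structure (e.g. image-cognition correlations
  within groups) is absent.
* Mixed-model inference is asymptotic (Wald z); no Satterthwaite or
  Kenward-Roger degrees of freedom.
* The classifier assumes the new cohort shares the atlas and preprocessing
  of the model-building cohort; no spatial normalization is implemented.
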