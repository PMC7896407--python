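"""Synthetic FDG-PET cohort generator with planted hypometabolic subtypes.

Generative model for subject *i* with subtype template delta(r):

    image_i(x) = g_i * base(r(x)) * (1 - s_i * delta(r(x))) * q_i^[x in pons] + eps(x)

* ``g_i`` — global uptake factor, log-normal with log-SD ``global_factor_sd``;
  a pure nuisance that global-mean scaling removes exactly.
* ``s_i`` — hypometabolism severity, Gamma(shape 4, mean per diagnostic
  group); scales the template's fractional reductions and creates
  overlapping severity distributions between dementia and prodromal cases.
* ``q_i`` — reference-region (pons) uptake variability, log-normal with
  log-SD ``ref_region_sd``, applied to pons voxels only. It makes
  pons-scaled regional values share a common subject-level factor, the
  dominant variance term in real SUVR data; without it the regional
  hypometabolism screen would flag every subject through the sheer number
  of independently noisy regions.
* ``eps`` — iid Gaussian voxel noise (SD ``voxel_noise_sd``) on labelled
  voxels.

Cognitively normal (CN) controls use delta = 0, as does the planted
``no_hypometabolism`` prodromal subtype. Setting all three noise scales
to zero and fixing severity makes the equation exactly invertible, which
the test-suite uses to pin the implementation.

Baseline covariates, cognitive composites, biomarkers and volumetrics are
drawn from per-group/subtype normal distributions whose means and SDs
default to the study-cohort tables this simulator emulates. Longitudinal
cognitive scores follow a linear mixed model (random intercept + slope);
progression to dementia follows proportional hazards with an exponential
(optionally Weibull) baseline, expressed on the CDR scale at discrete
visits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas, generate_atlas, _largest_remainder

AD_SUBTYPES = ("limbic_predominant", "typical", "cortical_predominant")
MCI_SUBTYPES = ("no_hypometabolism", "limbic_predominant", "typical",
                "cortical_predominant")
DOMAINS = ("MEM", "EF", "VS", "Lan")

GM_BASE = 1.3   # grey-matter baseline uptake relative to pons
PONS_BASE = 1.0
MAX_REDUCTION = 0.6  # severity x delta saturates here: even end-stage disease
                     # does not abolish more than ~60% of regional metabolism


class CohortDataError(ValueError):
    pass


@dataclass
class SubtypeTemplate:
    """Regional fractional uptake reductions defining one subtype."""

    name: str
    delta: dict[int, float]  # region_id -> reduction in [0, 0.5]

    def __post_init__(self) -> None:
        for rid, d in self.delta.items():
            if not 0.0 <= d <= 0.5:
                raise ValueError(f"delta[{rid}]={d} outside [0, 0.5]")
        if self.name == "no_hypometabolism" and any(d > 0.02 for d in self.delta.values()):
            raise ValueError("no_hypometabolism template must have deltas <= 0.02")

    def delta_vector(self, atlas: LabelAtlas) -> np.ndarray:
        """Per-region delta over all atlas regions (0 where unspecified)."""
        out = np.zeros(len(atlas.regions) + 1)
        for rid, d in self.delta.items():
            out[rid] = d
        return out


def default_templates(atlas: LabelAtlas) -> dict[str, SubtypeTemplate]:
    """The three planted disease patterns plus the flat template.

    * ``typical`` — marked posterior temporo-parietal reduction with
      milder medial-temporal involvement.
    * ``limbic_predominant`` — strongest reduction in the medial temporal
      lobe, extending into frontal and anterior cortical areas.
    * ``cortical_predominant`` — widespread cortical and frontal
      reduction with the medial temporal lobe spared.
    """
    ids = {s: atlas.region_ids(s) for s in
           ("cortical", "medial_temporal", "frontal", "posterior_temporo_parietal")}
    cort = np.sort(ids["cortical"])
    ant, post = cort[: len(cort) // 2], cort[len(cort) // 2:]

    def build(name, mt, frontal, ptp, cort_ant, cort_post):
        delta = {}
        for rid in ids["medial_temporal"]:
            delta[int(rid)] = mt
        for rid in ids["frontal"]:
            delta[int(rid)] = frontal
        for rid in ids["posterior_temporo_parietal"]:
            delta[int(rid)] = ptp
        for rid in ant:
            delta[int(rid)] = cort_ant
        for rid in post:
            delta[int(rid)] = cort_post
        return SubtypeTemplate(name, delta)

    templates = {
        "typical": build("typical", mt=0.10, frontal=0.00, ptp=0.30,
                         cort_ant=0.00, cort_post=0.14),
        "limbic_predominant": build("limbic_predominant", mt=0.34, frontal=0.12,
                                    ptp=0.02, cort_ant=0.10, cort_post=0.00),
        "cortical_predominant": build("cortical_predominant", mt=0.00, frontal=0.47,
                                      ptp=0.18, cort_ant=0.47, cort_post=0.50),
        "no_hypometabolism": SubtypeTemplate("no_hypometabolism", {}),
    }
    _check_distinct(templates, atlas)
    return templates


def _check_distinct(templates: dict[str, SubtypeTemplate], atlas: LabelAtlas,
                    min_gap: float = 0.05) -> None:
    disease = [t for n, t in templates.items() if n != "no_hypometabolism"]
    for i, a in enumerate(disease):
        for b in disease[i + 1:]:
            gap = np.abs(a.delta_vector(atlas) - b.delta_vector(atlas)).max()
            if gap < min_gap:
                raise ValueError(f"templates {a.name}/{b.name} not distinct "
                                 f"(max |delta difference| {gap:.3f} < {min_gap})")


# Baseline characteristics per (group, subtype): mean/SD pairs emulating the
# study cohort's printed tables; rates for binary variables. The prodromal
# cortical-predominant cell (n=3 in the source cohort, not tabulated) is an
# invented but plausible interpolation.
BASELINE_TABLES: dict[tuple[str, str | None], dict] = {
    ("CN", None): dict(age=(73.8, 6.5), female=0.50, education=(16.6, 2.5),
                       MMSE=(29.1, 1.2), MEM=(1.04, 0.62), EF=(0.92, 0.83),
                       VS=(0.23, 0.59), Lan=(0.89, 0.71), apoe4=0.28,
                       av45_suvr=(1.11, 0.18), csf_abeta=(1392, 663),
                       csf_ttau=(236, 92), csf_ptau=(22, 9),
                       hv=(4.97, 0.38), ctv=(87.39, 6.28), wmh=(6.1, 10.4)),
    ("AD", "limbic_predominant"): dict(age=(75.4, 6.9), female=0.49, education=(15.4, 3.1),
                                       MMSE=(23.4, 1.9), MEM=(-0.85, 0.55), EF=(-0.65, 0.86),
                                       VS=(-0.42, 0.80), Lan=(-0.63, 0.95), apoe4=0.81,
                                       av45_suvr=(1.43, 0.14), csf_abeta=(598, 163),
                                       csf_ttau=(374, 143), csf_ptau=(38, 16),
                                       hv=(4.05, 0.51), ctv=(75.84, 6.95), wmh=(8.0, 10.0)),
    ("AD", "typical"): dict(age=(73.2, 5.7), female=0.38, education=(15.5, 2.6),
                            MMSE=(23.2, 2.2), MEM=(-0.90, 0.49), EF=(-1.11, 0.89),
                            VS=(-0.67, 1.01), Lan=(-0.83, 0.88), apoe4=0.79,
                            av45_suvr=(1.47, 0.17), csf_abeta=(585, 225),
                            csf_ttau=(374, 154), csf_ptau=(37, 16),
                            hv=(4.10, 0.38), ctv=(73.99, 6.23), wmh=(5.8, 7.9)),
    ("AD", "cortical_predominant"): dict(age=(68.0, 7.7), female=0.50, education=(16.3, 2.6),
                                         MMSE=(22.0, 2.2), MEM=(-1.31, 0.44), EF=(-1.73, 0.81),
                                         VS=(-1.15, 1.08), Lan=(-1.11, 0.78), apoe4=0.58,
                                         av45_suvr=(1.40, 0.17), csf_abeta=(629, 169),
                                         csf_ttau=(402, 124), csf_ptau=(39, 14),
                                         hv=(4.46, 0.46), ctv=(70.04, 5.88), wmh=(8.1, 12.7)),
    ("MCI", "no_hypometabolism"): dict(age=(68.4, 6.6), female=0.60, education=(16.2, 2.8),
                                       MMSE=(28.2, 1.8), MEM=(0.57, 0.63), EF=(0.76, 0.91),
                                       VS=(0.08, 0.65), Lan=(0.60, 0.70), apoe4=0.68,
                                       av45_suvr=(1.31, 0.17), csf_abeta=(921, 437),
                                       csf_ttau=(315, 134), csf_ptau=(31, 15),
                                       hv=(4.86, 0.45), ctv=(89.87, 5.45), wmh=(4.9, 5.0)),
    ("MCI", "limbic_predominant"): dict(age=(76.1, 5.7), female=0.35, education=(15.7, 3.0),
                                        MMSE=(27.6, 1.8), MEM=(0.05, 0.61), EF=(0.00, 0.77),
                                        VS=(-0.06, 0.76), Lan=(-0.05, 0.74), apoe4=0.62,
                                        av45_suvr=(1.39, 0.17), csf_abeta=(736, 237),
                                        csf_ttau=(337, 137), csf_ptau=(34, 16),
                                        hv=(4.53, 0.51), ctv=(83.19, 6.48), wmh=(11.3, 12.8)),
    ("MCI", "typical"): dict(age=(71.7, 6.2), female=0.41, education=(16.4, 2.6),
                             MMSE=(27.3, 1.8), MEM=(-0.06, 0.65), EF=(0.15, 1.01),
                             VS=(-0.21, 0.67), Lan=(0.29, 0.79), apoe4=0.77,
                             av45_suvr=(1.43, 0.15), csf_abeta=(672, 214),
                             csf_ttau=(357, 144), csf_ptau=(37, 16),
                             hv=(4.57, 0.41), ctv=(82.93, 5.35), wmh=(6.8, 6.5)),
    # invented: prodromal cortical-predominant (source cell n=3, untabulated)
    ("MCI", "cortical_predominant"): dict(age=(68.0, 7.0), female=0.40, education=(16.3, 2.6),
                                          MMSE=(27.0, 1.8), MEM=(-0.10, 0.65), EF=(-0.30, 0.90),
                                          VS=(-0.30, 0.70), Lan=(0.10, 0.80), apoe4=0.55,
                                          av45_suvr=(1.42, 0.16), csf_abeta=(680, 210),
                                          csf_ttau=(360, 140), csf_ptau=(37, 16),
                                          hv=(4.70, 0.45), ctv=(79.0, 5.5), wmh=(7.0, 7.0)),
}

#: per-month decline slopes by subtype x cognitive domain (composite units);
#: ordering encodes the planted longitudinal findings: prodromal cases with
#: hypometabolism decline faster everywhere, the typical subtype declines
#: fastest in executive function while matching the limbic subtype on memory.
DEFAULT_DECLINE_SLOPES: dict[str, dict[str, float]] = {
    "no_hypometabolism": dict(MEM=-0.002, EF=-0.002, VS=-0.001, Lan=-0.002),
    "limbic_predominant": dict(MEM=-0.012, EF=-0.008, VS=-0.006, Lan=-0.008),
    "typical": dict(MEM=-0.012, EF=-0.018, VS=-0.012, Lan=-0.010),
    "cortical_predominant": dict(MEM=-0.014, EF=-0.025, VS=-0.015, Lan=-0.012),
}

DEFAULT_HAZARD_RATIOS = {"no_hypometabolism": 1.0, "limbic_predominant": 4.82,
                         "typical": 5.99, "cortical_predominant": 5.99}


@dataclass
class CohortConfig:
    """All simulator knobs; defaults are the emulated study conditions."""

    n_cn: int = 179
    n_ad: int = 177
    n_mci: int = 217
    # planted mixture proportions (sum to 1): AD over the three disease
    # subtypes; prodromal additionally includes the no-hypometabolism class
    subtype_proportions_ad: dict[str, float] = field(default_factory=lambda: {
        "limbic_predominant": 0.446, "typical": 0.486, "cortical_predominant": 0.068})
    subtype_proportions_mci: dict[str, float] = field(default_factory=lambda: {
        "no_hypometabolism": 57 / 217, "limbic_predominant": 108 / 217,
        "typical": 49 / 217, "cortical_predominant": 3 / 217})
    global_factor_sd: float = 0.15
    ref_region_sd: float = 0.08
    voxel_noise_sd: float = 0.08
    severity_shape: float = 4.0
    severity_mean_ad: float = 1.6
    severity_mean_mci: float = 1.2
    severity_fixed: bool = False  # use the group mean severity for everyone
    av45_missing_rate: float = 0.12
    # longitudinal
    hazard_ratios: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))
    baseline_hazard: float = 0.004   # events/month for the reference subtype
    weibull_shape: float = 1.0       # 1 = exponential
    decline_slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DECLINE_SLOPES.items()})
    random_intercept_sd: float = 0.40
    random_slope_sd: float = 0.005
    visit_noise_sd: float = 0.25
    followup_months: int = 72
    min_followup_months: int = 12
    visit_interval_months: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, props in (("subtype_proportions_ad", self.subtype_proportions_ad),
                            ("subtype_proportions_mci", self.subtype_proportions_mci)):
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in props.values()):
                raise ValueError(f"{name} must be non-negative")
        for sd in (self.global_factor_sd, self.ref_region_sd, self.voxel_noise_sd,
                   self.random_intercept_sd, self.random_slope_sd, self.visit_noise_sd):
            if sd < 0:
                raise ValueError("all SDs must be >= 0")
        if not self.severity_mean_ad > self.severity_mean_mci:
            raise ValueError("severity_mean_ad must exceed severity_mean_mci")
        if self.followup_months <= 0 or self.visit_interval_months <= 0:
            raise ValueError("follow-up and visit interval must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


def _subtype_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    names = list(proportions)
    counts = _largest_remainder(n, np.array([proportions[s] for s in names]))
    return dict(zip(names, (int(c) for c in counts)))


@dataclass
class CrossSectionalData:
    """Images + baseline table + full manifest of drawn parameters."""

    images: np.ndarray          # (n_subjects, nx, ny, nz) float32, unsmoothed
    cohort: pd.DataFrame        # one row per subject
    manifest: dict


def _draw_baseline(rng: np.random.Generator, group: str, subtype: str | None) -> dict:
    tab = BASELINE_TABLES[(group, subtype if group != "CN" else None)]
    row = {}
    for var in ("age", "education", "MEM", "EF", "VS", "Lan", "av45_suvr",
                "csf_abeta", "csf_ttau", "csf_ptau", "hv", "ctv"):
        m, sd = tab[var]
        row[var] = rng.normal(m, sd)
    m, sd = tab["MMSE"]
    row["MMSE"] = int(np.clip(np.round(rng.normal(m, sd)), 0, 30))
    m, sd = tab["wmh"]
    row["wmh"] = max(0.1, rng.normal(m, sd))
    row["gender"] = "F" if rng.random() < tab["female"] else "M"
    row["apoe4"] = int(rng.random() < tab["apoe4"])
    # floors keep biomarkers physically meaningful despite normal draws
    row["age"] = float(np.clip(row["age"], 50, 95))
    row["education"] = float(np.clip(np.round(row["education"]), 6, 20))
    row["av45_suvr"] = max(0.7, row["av45_suvr"])
    for v in ("csf_abeta", "csf_ttau", "csf_ptau"):
        row[v] = max(5.0, row[v])
    row["hv"] = max(1.0, row["hv"])
    row["ctv"] = max(row["hv"] + 10.0, row["ctv"])
    row["tiv"] = float(rng.normal(1450, 140))
    row["DIFF"] = row["MEM"] - row["EF"]
    return row


def generate_cross_sectional(atlas: LabelAtlas,
                             templates: dict[str, SubtypeTemplate],
                             config: CohortConfig) -> CrossSectionalData:
    """Simulate unsmoothed baseline images and the subject table.

    Subtype counts follow the configured proportions under
    largest-remainder rounding, so count-based checks are exact. The
    manifest records every drawn subject-level parameter (g, q, s) plus
    the config and templates; with zero noise the generative equation is
    invertible from the manifest.
    """
    rng = np.random.default_rng([config.seed, 101])
    plan: list[tuple[str, str | None]] = [("CN", None)] * config.n_cn
    for subtype, cnt in _subtype_counts(config.n_ad, config.subtype_proportions_ad).items():
        plan += [("AD", subtype)] * cnt
    for subtype, cnt in _subtype_counts(config.n_mci, config.subtype_proportions_mci).items():
        plan += [("MCI", subtype)] * cnt

    labels_flat = atlas.labels.ravel()
    labelled = labels_flat > 0
    pons_vox = labels_flat == atlas.pons_id
    base = np.where(pons_vox, PONS_BASE, np.where(labelled, GM_BASE, 0.0))

    region_delta = {name: t.delta_vector(atlas) for name, t in templates.items()}
    severity_mean = {"CN": 0.0, "AD": config.severity_mean_ad,
                     "MCI": config.severity_mean_mci}

    n = len(plan)
    images = np.zeros((n,) + atlas.shape, dtype=np.float32)
    rows = []
    counters = {"CN": 0, "AD": 0, "MCI": 0}
    for i, (group, subtype) in enumerate(plan):
        counters[group] += 1
        sid = f"{group}_{counters[group]:03d}"
        g = float(np.exp(rng.normal(0.0, config.global_factor_sd)))
        q = float(np.exp(rng.normal(0.0, config.ref_region_sd)))
        if group == "CN":
            s = 0.0
        elif config.severity_fixed:
            s = severity_mean[group]
        else:
            mean = severity_mean[group]
            s = float(rng.gamma(config.severity_shape, mean / config.severity_shape))
        tmpl = "no_hypometabolism" if group == "CN" else subtype
        delta_vox = region_delta[tmpl][labels_flat]
        # reductions capped at 90%: uptake cannot go negative for extreme severity
        signal = g * base * (1.0 - np.minimum(s * delta_vox, MAX_REDUCTION))
        signal = np.where(pons_vox, signal * q, signal)
        if config.voxel_noise_sd > 0:
            noise = rng.normal(0.0, config.voxel_noise_sd, size=signal.shape)
            signal = signal + np.where(labelled, noise, 0.0)
        images[i] = signal.reshape(atlas.shape).astype(np.float32)

        row = dict(subject_id=sid, group=group,
                   true_subtype=subtype if group != "CN" else None,
                   severity=s, global_factor=g, pons_factor=q)
        row.update(_draw_baseline(rng, group, subtype))
        rows.append(row)

    cohort = pd.DataFrame(rows)
    if not ((cohort["tiv"] > cohort["ctv"]) & (cohort["ctv"] > cohort["hv"])
            & (cohort["hv"] > 0)).all():
        raise CohortDataError("volume ordering tiv > ctv > hv > 0 violated")
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "templates": {name: {str(k): v for k, v in t.delta.items()}
                      for name, t in templates.items()},
        "subjects": cohort[["subject_id", "group", "true_subtype", "severity",
                            "global_factor", "pons_factor"]].to_dict("records"),
        "base_uptake": {"gm": GM_BASE, "pons": PONS_BASE},
    }
    return CrossSectionalData(images=images, cohort=cohort, manifest=manifest)


def generate_longitudinal(cohort: pd.DataFrame, config: CohortConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate visit-level cognition and CDR for the prodromal group.

    Returns ``(visits, events)``. Domain scores follow
    ``baseline + slope(subtype, domain) * month + u0 + u1 * month + eps``.
    Progression (CDR 0.5 -> >= 1) times are Weibull with subtype hazard
    ratios acting proportionally; CDR is 0.5 before the event and 1.0
    from the first visit at or after it. Administrative censoring happens
    at a per-subject last visit drawn uniformly from the visit grid
    between ``min_followup_months`` and ``followup_months``.
    """
    rng = np.random.default_rng([config.seed, 202])
    mci = cohort[cohort["group"] == "MCI"]
    if mci.empty:
        raise CohortDataError("cohort contains no MCI subjects to follow")
    if mci["true_subtype"].isna().any():
        raise CohortDataError("every MCI subject needs an assigned subtype")

    grid = np.arange(0, config.followup_months + 1, config.visit_interval_months)
    last_choices = grid[(grid >= config.min_followup_months)]
    lam0 = config.baseline_hazard
    shape = config.weibull_shape

    visit_rows, event_rows = [], []
    for _, subj in mci.iterrows():
        subtype = subj["true_subtype"]
        hr = config.hazard_ratios[subtype]
        # Weibull PH: S(t) = exp(-(lam0 * t)^shape * HR)
        u = rng.random()
        t_event = (-np.log(u) / hr) ** (1.0 / shape) / lam0
        last = int(rng.choice(last_choices))
        months = grid[grid <= last]
        u0 = rng.normal(0.0, config.random_intercept_sd)
        u1 = rng.normal(0.0, config.random_slope_sd)
        baselines = {d: subj[d] for d in DOMAINS}
        slopes = config.decline_slopes[subtype]
        for m in months:
            cdr = 0.5 if m < t_event else 1.0
            row = dict(subject_id=subj["subject_id"], month=int(m), cdr=cdr)
            for d in DOMAINS:
                noise = rng.normal(0.0, config.visit_noise_sd) if config.visit_noise_sd > 0 else 0.0
                row[d] = baselines[d] + (slopes[d] + u1) * m + u0 + noise
            visit_rows.append(row)
        observed = t_event <= last
        event_rows.append(dict(subject_id=subj["subject_id"], subtype=subtype,
                               event_time=float(t_event), last_visit=last,
                               observed=bool(observed)))
    visits = pd.DataFrame(visit_rows)
    events = pd.DataFrame(event_rows)
    return visits, events


# ----------------------------------------------------------------------
# cohort I/O


def write_cohort(data: CrossSectionalData, atlas: LabelAtlas, out_dir: str | Path,
                 visits: pd.DataFrame | None = None,
                 events: pd.DataFrame | None = None) -> dict:
    """Write NIfTI volumes, CSV tables and a JSON manifest; return the manifest."""
    import nibabel as nib

    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {out}: {exc}") from exc

    if visits is not None:
        missing = set(visits["subject_id"]) - set(data.cohort["subject_id"])
        if missing:
            raise CohortDataError(f"visit subjects absent from cohort: {sorted(missing)[:5]}")

    affine = np.diag([atlas.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), affine), out / "atlas.nii")
    nib.save(nib.Nifti1Image(atlas.gm_mask.astype(np.uint8), affine), out / "gm_mask.nii")
    atlas.regions.to_csv(out / "regions.csv", index=False)

    image_files = {}
    for i, sid in enumerate(data.cohort["subject_id"]):
        fn = f"images/{sid}.nii"
        nib.save(nib.Nifti1Image(data.images[i].astype(np.float32), affine), out / fn)
        image_files[sid] = fn
    data.cohort.to_csv(out / "cohort.csv", index=False)
    if visits is not None:
        visits.to_csv(out / "visits.csv", index=False)
    if events is not None:
        events.to_csv(out / "events.csv", index=False)

    manifest = dict(data.manifest)
    manifest["files"] = dict(atlas="atlas.nii", gm_mask="gm_mask.nii",
                             regions="regions.csv", cohort="cohort.csv",
                             images=image_files,
                             visits="visits.csv" if visits is not None else None,
                             events="events.csv" if events is not None else None)
    manifest["voxel_size_mm"] = atlas.voxel_size_mm
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(out_dir: str | Path) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Round-trip reader for :func:`write_cohort` output."""
    import nibabel as nib

    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    cohort = pd.read_csv(out / "cohort.csv")
    images = []
    for sid in cohort["subject_id"]:
        img = nib.load(out / manifest["files"]["images"][sid])
        images.append(np.asarray(img.dataobj, dtype=np.float32))
    return np.stack(images), cohort, manifest


def regenerate_from_manifest(manifest: dict) -> CrossSectionalData:
    """Rebuild the identical cohort from a stored manifest (reproducibility)."""
    config = CohortConfig.from_dict(manifest["config"])
    atlas = generate_atlas(seed=config.seed)
    templates = {name: SubtypeTemplate(name, {int(k): v for k, v in d.items()})
                 for name, d in manifest["templates"].items()}
    return generate_cross_sectional(atlas, templates, config)
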