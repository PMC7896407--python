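"""Two-stage classification of prodromal subjects against a SubtypeModel.

Stage 1 (screen): a subject shows regional hypometabolism if at least
one screened region's pons-scaled mean lies at or below the control
group's mean minus one control SD. Subjects with no such region form the
``no_hypometabolism`` class. Stage 2 (matching): the remaining subjects
are assigned to the dementia-derived subtype whose mean globally scaled
profile is nearest in Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .cluster import SubtypeModel
from .preprocess import (GLOBAL, PONS, RegionalVector, VoxelProfile,
                         extract_regional_means, scale_global, scale_reference,
                         smooth_gaussian)

logger = logging.getLogger(__name__)

NO_HYPO = "no_hypometabolism"

#: flag threshold in control SD units below the control mean
SCREEN_SD_THRESHOLD = 1.0


@dataclass
class ScreenResult:
    subject_id: str | None
    z_scores: pd.Series              # index region_id
    flagged_regions: set[int]
    passes_screen: bool


@dataclass
class Assignment:
    subject_id: str | None
    subtype: str
    distances: dict[str, float]
    screen: ScreenResult | None = None


def screen_hypometabolism(regional: RegionalVector, model: SubtypeModel) -> ScreenResult:
    """Flag regions at or below (CN mean - 1 CN SD); inclusive boundary."""
    if regional.scaling != PONS:
        raise ValueError("screening requires pons-scaled regional means")
    ref = model.cn_regional_reference
    if ref is None:
        raise ValueError("SubtypeModel carries no CN regional reference")
    missing = set(ref.index) - set(regional.values.index)
    if missing:
        raise ValueError(f"regions missing from regional vector: {sorted(missing)[:5]}")
    vals = regional.values.loc[ref.index]
    z = (vals - ref["mean"]) / ref["sd"]
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores in screen")
    flagged = set(z.index[z <= -SCREEN_SD_THRESHOLD].tolist())
    return ScreenResult(subject_id=regional.subject_id, z_scores=z,
                        flagged_regions=flagged, passes_screen=bool(flagged))


def classify_nearest_centroid(profile: VoxelProfile, model: SubtypeModel) -> Assignment:
    """Assign the subtype with minimal Euclidean distance to its centroid.

    Exact ties are broken by the model's fixed subtype order (first
    wins) and logged.
    """
    if profile.scaling != GLOBAL:
        raise ValueError("matching requires a globally scaled profile")
    x = profile.values
    if x.shape[0] != model.centroids.shape[1]:
        raise ValueError("profile length does not match centroid length")
    dists = np.linalg.norm(model.centroids - x[None, :], axis=1)
    best = int(np.argmin(dists))  # argmin returns the first minimum: the tie rule
    if np.sum(dists == dists[best]) > 1:
        logger.info("nearest-centroid tie for subject %s broken by subtype order",
                    profile.subject_id)
    return Assignment(subject_id=profile.subject_id,
                      subtype=model.subtype_names[best],
                      distances={s: float(d) for s, d in
                                 zip(model.subtype_names, dists)})


def build_cn_regional_reference(cn_images: np.ndarray, atlas: LabelAtlas,
                                region_set: str | list[str] | None = None,
                                fwhm_mm: float = 8.0) -> pd.DataFrame:
    """CN mean/SD of pons-scaled regional means (the screen's reference)."""
    rows = []
    for vol in cn_images:
        sm = (smooth_gaussian(vol, fwhm_mm, atlas.voxel_size_mm) if fwhm_mm
              else np.asarray(vol, float))
        prof = scale_reference(sm, atlas)
        rows.append(extract_regional_means(prof, atlas, region_set).values)
    mat = pd.DataFrame(rows)
    ref = pd.DataFrame({"mean": mat.mean(axis=0), "sd": mat.std(axis=0, ddof=1)})
    ref.index.name = "region_id"
    return ref


def classify_cohort(images: np.ndarray, subject_ids: list[str], atlas: LabelAtlas,
                    model: SubtypeModel, region_set: str | list[str] | None = None,
                    fwhm_mm: float = 8.0) -> pd.DataFrame:
    """Screen + nearest-centroid assignment for a whole (prodromal) cohort.

    ``images`` are unsmoothed volumes; smoothing, pons scaling (for the
    screen) and global scaling (for the matching) are applied here so
    both representations derive from the same input. Returns one row per
    subject with the screen outcome, the assigned subtype and all
    centroid distances. An empty cohort yields an empty table.
    """
    cols = (["subject_id", "screen_pass", "flagged_region_count", "subtype"]
            + [f"dist_{s}" for s in model.subtype_names])
    rows = []
    for i, sid in enumerate(subject_ids):
        sm = (smooth_gaussian(images[i], fwhm_mm, atlas.voxel_size_mm) if fwhm_mm
              else np.asarray(images[i], float))
        pons_prof = scale_reference(sm, atlas, subject_id=sid)
        regional = extract_regional_means(pons_prof, atlas, region_set)
        screen = screen_hypometabolism(regional, model)
        row = dict(subject_id=sid, screen_pass=screen.passes_screen,
                   flagged_region_count=len(screen.flagged_regions))
        if screen.passes_screen:
            glob_prof = VoxelProfile(scale_global(pons_prof.values), GLOBAL, sid)
            assign = classify_nearest_centroid(glob_prof, model)
            row["subtype"] = assign.subtype
            for s, d in assign.distances.items():
                row[f"dist_{s}"] = d
        else:
            row["subtype"] = NO_HYPO
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def subtype_frequencies(assignments: pd.DataFrame) -> pd.Series:
    """Fraction of the cohort per assigned subtype (includes no_hypometabolism)."""
    if assignments.empty:
        return pd.Series(dtype=float)
    return assignments["subtype"].value_counts(normalize=True)
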