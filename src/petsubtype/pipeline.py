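"""End-to-end orchestration of the subtyping analysis on a cohort.

Mirrors the study workflow: smooth all images; Ward-cluster the
globally scaled dementia profiles and select k by internal criteria;
name the recovered clusters by similarity to the planted (or analyst
supplied) templates; build the subtype model (centroids + CN regional
reference); screen and classify the prodromal group; hand the
assignments to the outcome models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LabelAtlas
from .classify import build_cn_regional_reference, classify_cohort
from .cluster import SubtypeClustering, SubtypeClusteringResults, SubtypeModel
from .preprocess import GLOBAL, ProfileSet, scale_global, smooth_gaussian
from .simulate import SubtypeTemplate, GM_BASE


def load_atlas(cohort_dir: str | Path) -> LabelAtlas:
    """Re-read a written atlas (labels + region table) from a cohort directory."""
    import nibabel as nib

    d = Path(cohort_dir)
    labels = np.asarray(nib.load(d / "atlas.nii").dataobj).astype(np.int32)
    regions = pd.read_csv(d / "regions.csv")
    gm = np.asarray(nib.load(d / "gm_mask.nii").dataobj).astype(bool)
    import json

    with open(d / "manifest.json") as fh:
        vox = json.load(fh)["voxel_size_mm"]
    return LabelAtlas(labels=labels, regions=regions, voxel_size_mm=vox, gm_mask=gm)


def smoothed_global_profiles(images: np.ndarray, subject_ids: list[str],
                             atlas: LabelAtlas, fwhm_mm: float = 8.0) -> ProfileSet:
    """Smooth, mask to grey matter, and global-mean scale a set of volumes."""
    rows = []
    for vol in images:
        sm = (smooth_gaussian(vol, fwhm_mm, atlas.voxel_size_mm) if fwhm_mm
              else np.asarray(vol, float))
        rows.append(sm.ravel()[atlas.gm_flat_indices()])
    X = scale_global(np.asarray(rows))
    return ProfileSet(X, GLOBAL, list(subject_ids))


def template_profile(template: SubtypeTemplate, atlas: LabelAtlas) -> np.ndarray:
    """Globally scaled noise-free grey-matter profile a template generates."""
    delta = template.delta_vector(atlas)[atlas.region_labels_gm()]
    prof = GM_BASE * (1.0 - delta)
    return prof / prof.mean()


def match_clusters_to_templates(model_centroids: np.ndarray,
                                templates: dict[str, SubtypeTemplate],
                                atlas: LabelAtlas,
                                candidate_names: tuple[str, ...] = (
                                    "typical", "limbic_predominant",
                                    "cortical_predominant")) -> list[str]:
    """One-to-one cluster -> template naming by minimal centroid distance.

    Stands in for the analyst's visual naming of clusters from their
    effect-size maps; uses the Hungarian assignment on Euclidean
    distances between cluster centroids and the ideal template profiles.
    """
    from scipy.optimize import linear_sum_assignment

    names = list(candidate_names)[: model_centroids.shape[0]]
    ideals = np.array([template_profile(templates[n], atlas) for n in names])
    cost = np.linalg.norm(model_centroids[:, None, :] - ideals[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    out = [None] * model_centroids.shape[0]
    for r, c in zip(rows, cols):
        out[r] = names[c]
    for i, name in enumerate(out):  # more clusters than templates: keep generic ids
        if name is None:
            out[i] = f"cluster_{i + 1}"
    return out


def cluster_dementia_cohort(images: np.ndarray, cohort: pd.DataFrame,
                            atlas: LabelAtlas, k_range: tuple[int, int] = (2, 10),
                            k: int | None = None,
                            fwhm_mm: float = 8.0) -> SubtypeClusteringResults:
    ad = cohort[cohort["group"] == "AD"]
    profiles = smoothed_global_profiles(images[ad.index.to_numpy()],
                                        ad["subject_id"].tolist(), atlas, fwhm_mm)
    return SubtypeClustering(profiles).fit(k_range=k_range, k=k)


@dataclass
class PipelineResult:
    atlas: LabelAtlas
    cohort: pd.DataFrame
    visits: pd.DataFrame | None
    clustering: SubtypeClusteringResults
    subtype_model: SubtypeModel
    assignments: pd.DataFrame   # prodromal screen + subtype per subject


def run_pipeline_arrays(images: np.ndarray, cohort: pd.DataFrame, atlas: LabelAtlas,
                        templates: dict[str, SubtypeTemplate] | None = None,
                        visits: pd.DataFrame | None = None,
                        k: int | None = None,
                        k_range: tuple[int, int] = (2, 10),
                        fwhm_mm: float = 8.0,
                        screen_region_set=None) -> PipelineResult:
    """Full analysis on in-memory arrays (the acceptance-script entry point)."""
    clustering = cluster_dementia_cohort(images, cohort, atlas, k_range=k_range,
                                         k=k, fwhm_mm=fwhm_mm)
    cn = cohort[cohort["group"] == "CN"]
    cn_ref = build_cn_regional_reference(images[cn.index.to_numpy()], atlas,
                                         region_set=screen_region_set,
                                         fwhm_mm=fwhm_mm)
    names = None
    if templates is not None and clustering.k <= 3:
        names = match_clusters_to_templates(
            clustering.to_subtype_model().centroids, templates, atlas)
    model = clustering.to_subtype_model(names=names, cn_regional_reference=cn_ref)
    mci = cohort[cohort["group"] == "MCI"]
    assignments = classify_cohort(images[mci.index.to_numpy()],
                                  mci["subject_id"].tolist(), atlas, model,
                                  region_set=screen_region_set, fwhm_mm=fwhm_mm)
    return PipelineResult(atlas=atlas, cohort=cohort, visits=visits,
                          clustering=clustering, subtype_model=model,
                          assignments=assignments)


def run_pipeline(cohort_dir: str | Path, k: int | None = None,
                 k_range: tuple[int, int] = (2, 10),
                 fwhm_mm: float = 8.0) -> PipelineResult:
    """Run the full analysis on a cohort directory written by ``write_cohort``."""
    from .simulate import read_cohort

    images, cohort, manifest = read_cohort(cohort_dir)
    atlas = load_atlas(cohort_dir)
    templates = {name: SubtypeTemplate(name, {int(r): v for r, v in d.items()})
                 for name, d in manifest.get("templates", {}).items()}
    visits_path = Path(cohort_dir) / "visits.csv"
    visits = pd.read_csv(visits_path) if visits_path.exists() else None
    return run_pipeline_arrays(images, cohort, atlas, templates or None,
                               visits=visits, k=k, k_range=k_range, fwhm_mm=fwhm_mm)
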