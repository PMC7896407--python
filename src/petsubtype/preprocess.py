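"""PET image preprocessing: smoothing, intensity scaling, regional summaries.

Two scaling conventions are used downstream and must not be confused:

* **global-mean scaling** — each subject's in-mask values divided by their
  own mean, so profiles encode the regional *pattern* irrespective of
  overall hypometabolism severity. Used for clustering and for
  nearest-centroid matching.
* **pons scaling** — values divided by the mean signal in the pons
  reference region, preserving absolute hypometabolism relative to a
  region spared by the disease. Used for group contrasts and for the
  regional hypometabolism screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelAtlas

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = fwhm * this

RAW, GLOBAL, PONS = "raw", "global", "pons"


class ScalingError(ValueError):
    """Non-positive or degenerate scaling divisor."""


@dataclass
class VoxelProfile:
    """One subject's in-mask intensities as a flat vector plus a scaling tag."""

    values: np.ndarray
    scaling: str
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite values")
        if self.scaling not in (RAW, GLOBAL, PONS):
            raise ValueError(f"unknown scaling tag {self.scaling!r}")


@dataclass
class ProfileSet:
    """Subject x voxel matrix with a shared scaling tag (rows align with ids)."""

    X: np.ndarray
    scaling: str
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.subject_ids):
            raise ValueError("X must be 2-D with one row per subject id")


@dataclass
class RegionalVector:
    """Per-region mean intensities with the scaling tag propagated."""

    values: pd.Series  # index = region_id
    scaling: str
    subject_id: str | None = None


def smooth_gaussian(volume: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float) -> np.ndarray:
    """Separable Gaussian smoothing with sigma = fwhm / (2*sqrt(2*ln 2)).

    The kernel is truncated at 4 sigma and the volume is zero-padded at
    its boundaries, so smoothed outputs are bit-reproducible. ``fwhm_mm``
    of 0 returns the input unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if np.ndim(voxel_size_mm) != 0:
        raise ValueError("anisotropic voxel sizes require per-axis fwhm; not supported")
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm == 0:
        return np.array(volume, dtype=float, copy=True)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma_vox,
                                   mode="constant", cval=0.0, truncate=4.0)


def scale_global(profile: VoxelProfile | np.ndarray) -> VoxelProfile | np.ndarray:
    """Divide a profile (or each row of a matrix) by its in-mask mean.

    Output rows have mean exactly 1; the operation is idempotent and
    invariant to positive rescaling of the input, which is what makes the
    clustering stage blind to overall severity.
    """
    if isinstance(profile, VoxelProfile):
        scaled = scale_global(profile.values)
        return VoxelProfile(scaled, GLOBAL, profile.subject_id)
    X = np.asarray(profile, dtype=float)
    means = X.mean(axis=-1, keepdims=True)
    if np.any(means <= 0):
        raise ScalingError("global mean must be positive")
    return X / means


def scale_profile_set(profiles: ProfileSet) -> ProfileSet:
    """Global-mean scale every row of a :class:`ProfileSet`."""
    return ProfileSet(scale_global(profiles.X), GLOBAL, list(profiles.subject_ids))


def scale_reference(volume: np.ndarray, atlas: LabelAtlas,
                    subject_id: str | None = None) -> VoxelProfile:
    """Scale in-mask voxels by the mean pons signal (pons-scaled profile)."""
    vol = np.asarray(volume, dtype=float)
    if vol.shape != atlas.shape:
        raise ValueError("volume shape does not match atlas")
    pons_vals = vol[atlas.labels == atlas.pons_id]
    if pons_vals.size == 0:
        raise ScalingError("pons reference region is empty")
    divisor = pons_vals.mean()
    if divisor <= 0:
        raise ScalingError("pons reference mean must be positive")
    values = vol.ravel()[atlas.gm_flat_indices()] / divisor
    return VoxelProfile(values, PONS, subject_id)


def extract_profile(volume: np.ndarray, atlas: LabelAtlas,
                    subject_id: str | None = None) -> VoxelProfile:
    """Raw in-mask profile in the atlas's fixed voxel order."""
    vol = np.asarray(volume, dtype=float)
    if vol.shape != atlas.shape:
        raise ValueError("volume shape does not match atlas")
    return VoxelProfile(vol.ravel()[atlas.gm_flat_indices()], RAW, subject_id)


def extract_regional_means(profile: VoxelProfile, atlas: LabelAtlas,
                           region_set: str | list[str] | None = None) -> RegionalVector:
    """Unweighted per-region voxel means of an in-mask profile."""
    if profile.values.shape[0] != atlas.n_gm_voxels:
        raise ValueError("profile length does not match atlas gm mask")
    wanted = atlas.region_ids(region_set)
    if wanted.size == 0:
        raise KeyError(f"no regions in set {region_set!r}")
    gm_labels = atlas.region_labels_gm()
    sums = np.bincount(gm_labels, weights=profile.values, minlength=gm_labels.max() + 2)
    counts = np.bincount(gm_labels, minlength=gm_labels.max() + 2)
    if np.any(counts[wanted] == 0):
        missing = wanted[counts[wanted] == 0]
        raise ValueError(f"regions with zero in-mask voxels: {missing.tolist()}")
    means = pd.Series(sums[wanted] / counts[wanted], index=pd.Index(wanted, name="region_id"))
    return RegionalVector(means, profile.scaling, profile.subject_id)


def regional_ratio(regional: RegionalVector, numerator_set: list[int] | np.ndarray,
                   denominator_set: list[int] | np.ndarray) -> float:
    """Ratio of mean regional signal between two region groups.

    Used for the inferior-to-medial-temporal metabolism ratio that
    separates limbic-predominant from typical hypometabolism patterns.
    """
    num_ids = np.asarray(numerator_set)
    den_ids = np.asarray(denominator_set)
    if num_ids.size == 0 or den_ids.size == 0:
        raise ValueError("both region sets must be non-empty")
    missing = set(np.concatenate([num_ids, den_ids]).tolist()) - set(regional.values.index)
    if missing:
        raise KeyError(f"regions missing from regional vector: {sorted(missing)}")
    den = regional.values.loc[den_ids].mean()
    if den <= 0:
        raise ScalingError("denominator regional mean must be positive")
    return float(regional.values.loc[num_ids].mean() / den)
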