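"""Synthetic label atlas for FDG-PET simulation.

The atlas emulates, at toy scale, a cortical parcellation plus a pons
reference region: an ellipsoidal "grey matter" volume partitioned into
compact parcels, each assigned to one of four anatomical sets
(``cortical``, ``medial_temporal``, ``frontal``,
``posterior_temporo_parietal``), and a small pons block placed below the
grey matter. The pons is used for reference-region intensity scaling and
is therefore kept disjoint from the grey-matter mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_SETS = ("cortical", "medial_temporal", "frontal", "posterior_temporo_parietal")
PONS_SET = "pons"

#: minimum voxels a parcel must have for regional means to be meaningful
MIN_REGION_VOXELS = 8


class AtlasSizingError(ValueError):
    """Grid too small to give every parcel its minimum voxel count."""


@dataclass
class LabelAtlas:
    """Integer label volume plus a region table.

    Attributes
    ----------
    labels : ndarray of int, 3-D
        0 is background; region ids are contiguous from 1.
    regions : DataFrame with columns ``region_id``, ``name``, ``set``, ``n_voxels``
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    gm_mask : ndarray of bool, 3-D
        Union of all non-pons regions.
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: float
    gm_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def pons_id(self) -> int:
        return int(self.regions.loc[self.regions["set"] == PONS_SET, "region_id"].iloc[0])

    @property
    def n_gm_voxels(self) -> int:
        return int(self.gm_mask.sum())

    def region_ids(self, region_set: str | list[str] | None = None) -> np.ndarray:
        """Region ids belonging to one set, a list of sets, or all non-pons sets."""
        if region_set is None:
            sel = self.regions["set"] != PONS_SET
        else:
            sets = [region_set] if isinstance(region_set, str) else list(region_set)
            unknown = set(sets) - set(REGION_SETS) - {PONS_SET}
            if unknown:
                raise KeyError(f"unknown region set(s): {sorted(unknown)}")
            sel = self.regions["set"].isin(sets)
        return self.regions.loc[sel, "region_id"].to_numpy()

    def gm_flat_indices(self) -> np.ndarray:
        """Flat indices (C order) of grey-matter voxels; fixes profile ordering."""
        return np.flatnonzero(self.gm_mask.ravel())

    def region_labels_gm(self) -> np.ndarray:
        """Label of each grey-matter voxel, aligned with :meth:`gm_flat_indices`."""
        return self.labels.ravel()[self.gm_flat_indices()]

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ids = self.regions["region_id"].to_numpy()
        if not np.array_equal(np.sort(ids), np.arange(1, len(ids) + 1)):
            raise ValueError("region ids must be unique and contiguous from 1")
        if (self.regions["set"] == PONS_SET).sum() != 1:
            raise ValueError("atlas must contain exactly one pons region")
        pons = self.labels == self.pons_id
        if np.logical_and(pons, self.gm_mask).any():
            raise ValueError("pons region must be disjoint from gm_mask")
        non_pons = np.logical_and(self.labels > 0, ~pons)
        if not np.array_equal(non_pons, self.gm_mask):
            raise ValueError("gm_mask must equal the union of non-pons regions")
        counts = np.bincount(self.labels.ravel(), minlength=len(ids) + 1)
        cortical = self.regions.loc[self.regions["set"] == "cortical", "region_id"]
        if (counts[cortical.to_numpy()] < MIN_REGION_VOXELS).any():
            raise ValueError(f"every cortical region needs >= {MIN_REGION_VOXELS} voxels")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer apportionment of `total` by `weights` (largest-remainder rule)."""
    weights = np.asarray(weights, dtype=float)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    if remainder:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:remainder]] += 1
    return counts


def generate_atlas(
    grid_dims: tuple[int, int, int] = (24, 28, 24),
    n_cortical: int = 48,
    n_medial_temporal: int = 6,
    n_frontal: int = 10,
    n_posterior: int = 12,
    voxel_size_mm: float = 4.0,
    seed: int = 0,
) -> LabelAtlas:
    """Build a deterministic synthetic atlas on a 3-D grid.

    Grey matter is an axis-aligned ellipsoid partitioned into near-equal
    compact parcels by chunking voxels along the anterior-posterior axis;
    the anterior chunks form the frontal set, the posterior chunks the
    posterior temporo-parietal set, inferior mid chunks the
    medial-temporal set, and the remainder the generic cortical set. A
    2x2x2 pons block sits below the ellipsoid. The construction is fully
    deterministic; `seed` is accepted for interface symmetry with the
    generators and does not alter the output.

    Raises
    ------
    AtlasSizingError
        If the grey-matter volume cannot give every parcel at least
        :data:`MIN_REGION_VOXELS` voxels.
    """
    nx, ny, nz = (int(d) for d in grid_dims)
    if min(nx, ny, nz) < 12:
        raise AtlasSizingError("each grid dimension must be >= 12")
    if n_cortical < 4:
        raise ValueError("need at least 4 cortical regions")
    for n, what in ((n_medial_temporal, "medial_temporal"), (n_frontal, "frontal"),
                    (n_posterior, "posterior_temporo_parietal")):
        if n < 1:
            raise ValueError(f"need at least 1 {what} region")

    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    # ellipsoid leaves a 2-voxel margin laterally and 4 inferior voxels free
    ax, ay, az = nx / 2.0 - 2, ny / 2.0 - 2, nz / 2.0 - 4
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    gm = (((ii - cx) / ax) ** 2 + ((jj - cy) / ay) ** 2 + ((kk - cz) / az) ** 2) <= 1.0

    # pons: 2x2x2 block centred in x/y at the inferior free margin
    px, py, pz = int(cx), int(cy), 1
    pons_mask = np.zeros_like(gm)
    pons_mask[px:px + 2, py:py + 2, pz:pz + 2] = True
    gm &= ~pons_mask

    n_gm_regions = n_cortical + n_medial_temporal + n_frontal + n_posterior
    n_gm_vox = int(gm.sum())
    if n_gm_vox < n_gm_regions * MIN_REGION_VOXELS:
        raise AtlasSizingError(
            f"grid {grid_dims} has {n_gm_vox} grey-matter voxels; "
            f"{n_gm_regions} regions need >= {n_gm_regions * MIN_REGION_VOXELS}"
        )

    # order gm voxels anterior->posterior, then inferior->superior, then lateral
    coords = np.column_stack(np.nonzero(gm))  # (x, y, z)
    order = np.lexsort((coords[:, 0], coords[:, 2], coords[:, 1]))  # y major, z, x
    coords = coords[order]

    sizes = _largest_remainder(n_gm_vox, np.ones(n_gm_regions))
    bounds = np.concatenate(([0], np.cumsum(sizes)))

    # chunk index -> anatomical set, by position along the y (AP) axis
    set_of_chunk = np.array(["cortical"] * n_gm_regions, dtype=object)
    set_of_chunk[:n_frontal] = "frontal"
    set_of_chunk[n_gm_regions - n_posterior:] = "posterior_temporo_parietal"
    mid = n_frontal + (n_gm_regions - n_frontal - n_posterior - n_medial_temporal) // 2
    set_of_chunk[mid:mid + n_medial_temporal] = "medial_temporal"

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    rows = []
    counters = {s: 0 for s in REGION_SETS}
    for chunk in range(n_gm_regions):
        rid = chunk + 1
        vox = coords[bounds[chunk]:bounds[chunk + 1]]
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = rid
        s = set_of_chunk[chunk]
        counters[s] += 1
        rows.append((rid, f"{s}_{counters[s]:02d}", s, len(vox)))
    pons_id = n_gm_regions + 1
    labels[pons_mask] = pons_id
    rows.append((pons_id, "pons", PONS_SET, int(pons_mask.sum())))

    regions = pd.DataFrame(rows, columns=["region_id", "name", "set", "n_voxels"])
    return LabelAtlas(labels=labels, regions=regions, voxel_size_mm=float(voxel_size_mm),
                      gm_mask=gm)
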