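"""Ward hierarchical clustering of metabolic profiles and cluster-number selection.

The subtyping model is agglomerative clustering under Ward's criterion:
at every step, merge the pair of clusters (A, B) whose union least
increases the total within-cluster sum of squared Euclidean distances,

    dSSE(A, B) = n_A * n_B / (n_A + n_B) * ||c_A - c_B||^2,

with c the cluster centroids. Merge costs are stored as dSSE itself.
Some implementations report dendrogram heights as sqrt(2 * dSSE); the
mapping is monotone, so tree topology and all cuts are identical
(:func:`cost_to_height` converts). Ward's criterion is reducible, so the
sequence of merge costs is non-decreasing; this is asserted on every
tree, and the costs obey a conservation law: their sum equals the total
SSE of the data about its grand centroid.

The number of clusters is chosen by internal validity criteria computed
on dendrogram cuts: the silhouette coefficient (higher better, primary)
and the Davies-Bouldin index (lower better, secondary). When the two
disagree the disagreement is reported, never silently resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .preprocess import GLOBAL, ProfileSet


class DegenerateMetricError(ValueError):
    """Distinct clusters with coincident centroids make the index undefined."""


@dataclass
class LinkageTree:
    """Ordered Ward merge records.

    Leaves are numbered ``0 .. n_leaves-1``; the node created by merge
    ``t`` gets id ``n_leaves + t`` (scipy convention). Each merge stores
    the two merged node ids (smaller first), the Ward cost dSSE, and the
    size of the merged cluster.
    """

    merges: list[tuple[int, int, float, int]]
    n_leaves: int

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a tree over n leaves must have n-1 merges")
        costs = self.costs
        if costs.size and np.any(np.diff(costs) < -1e-8 * max(costs.max(), 1.0)):
            raise AssertionError("Ward merge costs must be non-decreasing (reducibility)")
        if self.merges and self.merges[-1][3] != self.n_leaves:
            raise ValueError("final merge must contain all leaves")

    @property
    def costs(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges], dtype=float)

    def total_cost(self) -> float:
        """Sum of merge costs; equals total SSE about the grand centroid."""
        return float(self.costs.sum())

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix with heights sqrt(2*dSSE) for scipy/MATLAB cross-checks."""
        Z = np.empty((len(self.merges), 4))
        for t, (a, b, cost, size) in enumerate(self.merges):
            Z[t] = (a, b, cost_to_height(cost), size)
        return Z


def cost_to_height(cost: float | np.ndarray) -> float | np.ndarray:
    """Convert a dSSE merge cost to the sqrt(2*dSSE) dendrogram height."""
    return np.sqrt(2.0 * np.asarray(cost, dtype=float))


def ward_linkage(profiles: np.ndarray) -> LinkageTree:
    """Agglomerative Ward clustering via the Lance-Williams recurrence.

    Ties in the minimum merge cost are broken by the lexicographically
    smallest ``(min_node_id, max_node_id)`` pair, making the tree
    deterministic. O(n^3) time, O(n^2) memory; ample for cohort-sized n.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 profiles")
    if not np.all(np.isfinite(X)):
        raise ValueError("profiles contain non-finite values")

    n_nodes = 2 * n - 1
    # cost[i, j] = dSSE of merging active nodes i and j
    cost = np.full((n_nodes, n_nodes), np.inf)
    initial = squareform(0.5 * pdist(X, metric="sqeuclidean"))
    cost[:n, :n] = initial
    np.fill_diagonal(cost, np.inf)
    size = np.zeros(n_nodes, dtype=int)
    size[:n] = 1
    active = np.zeros(n_nodes, dtype=bool)
    active[:n] = True

    merges: list[tuple[int, int, float, int]] = []
    for t in range(n - 1):
        ids = np.flatnonzero(active)
        sub = cost[np.ix_(ids, ids)]
        m = sub.min()
        # smallest (min_id, max_id) among all minimal-cost pairs
        ti, tj = np.nonzero(sub <= m)
        pairs = sorted((ids[a], ids[b]) for a, b in zip(ti, tj) if ids[a] < ids[b])
        i, j = pairs[0]
        new = n + t
        ni, nj = size[i], size[j]
        merges.append((i, j, float(cost[i, j]), int(ni + nj)))

        others = ids[(ids != i) & (ids != j)]
        nk = size[others]
        upd = ((ni + nk) * cost[i, others] + (nj + nk) * cost[j, others]
               - nk * cost[i, j]) / (ni + nj + nk)
        cost[new, others] = upd
        cost[others, new] = upd
        size[new] = ni + nj
        active[i] = active[j] = False
        active[new] = True

    return LinkageTree(merges=merges, n_leaves=n)


def cut_tree(tree: LinkageTree, k: int) -> np.ndarray:
    """Labels 1..k from undoing the last k-1 merges.

    Clusters are renumbered by decreasing size, ties broken by the
    smallest member leaf id.
    """
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    # replay merges, tracking membership by node id
    members: dict[int, list[int]] = {i: [i] for i in range(tree.n_leaves)}
    for t, (a, b, _, _) in enumerate(tree.merges[: tree.n_leaves - k]):
        members[tree.n_leaves + t] = members.pop(a) + members.pop(b)
    clusters = sorted(members.values(), key=lambda mem: (-len(mem), min(mem)))
    labels = np.empty(tree.n_leaves, dtype=int)
    for lab, mem in enumerate(clusters, start=1):
        labels[mem] = lab
    return labels


def _check_labels(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must match the number of profiles")
    groups = [np.flatnonzero(labels == u) for u in np.unique(labels)]
    if any(g.size == 0 for g in groups):
        raise ValueError("every cluster must be non-empty")
    return groups


def davies_bouldin(profiles: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index: mean over clusters of the worst
    (scatter_i + scatter_j) / centroid_distance_ij ratio. Lower is better."""
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = _check_labels(X, labels)
    k = len(groups)
    if k < 2:
        raise ValueError("Davies-Bouldin needs k >= 2")
    centroids = np.array([X[g].mean(axis=0) for g in groups])
    scatter = np.array([np.linalg.norm(X[g] - c, axis=1).mean()
                        for g, c in zip(groups, centroids)])
    M = cdist(centroids, centroids)
    off = ~np.eye(k, dtype=bool)
    if np.any(M[off] == 0):
        if np.all(scatter == 0):
            return 0.0  # exactly repeated points: clusters are points, index 0
        raise DegenerateMetricError("distinct clusters share a centroid")
    with np.errstate(divide="ignore"):
        R = (scatter[:, None] + scatter[None, :]) / np.where(off, M, np.inf)
    return float(np.mean(R.max(axis=1)))


def silhouette(profiles: np.ndarray, labels: np.ndarray,
               dists: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette scores.

    s(i) = (b - a) / max(a, b) with a the mean intra-cluster distance
    (excluding self) and b the smallest mean distance to another cluster.
    Singleton-cluster members score 0, as does the a = b = 0 degenerate
    case (Rousseeuw's conventions).
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = _check_labels(X, labels)
    if len(groups) < 2:
        raise ValueError("silhouette needs k >= 2")
    D = cdist(X, X) if dists is None else np.asarray(dists, dtype=float)
    n = X.shape[0]
    s = np.zeros(n)
    for gi, g in enumerate(groups):
        if g.size == 1:
            continue  # singleton convention: s = 0
        a = D[np.ix_(g, g)].sum(axis=1) / (g.size - 1)
        b = np.full(g.size, np.inf)
        for hj, h in enumerate(groups):
            if hj == gi:
                continue
            b = np.minimum(b, D[np.ix_(g, h)].mean(axis=1))
        denom = np.maximum(a, b)
        with np.errstate(invalid="ignore"):
            vals = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
        s[g] = vals
    return float(s.mean()), s


@dataclass
class ClusterSolution:
    """Dendrogram cuts evaluated over a range of k with both criteria."""

    criteria: pd.DataFrame  # columns: k, davies_bouldin, silhouette
    k_silhouette: int
    k_davies_bouldin: int
    labels: np.ndarray  # cut at k_silhouette (the primary recommendation)
    tree: LinkageTree

    @property
    def k(self) -> int:
        """Primary recommendation (silhouette-maximizing k)."""
        return self.k_silhouette

    @property
    def criteria_agree(self) -> bool:
        return self.k_silhouette == self.k_davies_bouldin


def select_k(profiles: np.ndarray, k_range: tuple[int, int] = (2, 10),
             tree: LinkageTree | None = None) -> ClusterSolution:
    """Evaluate dendrogram cuts for k in ``k_range`` (inclusive) and pick k.

    The silhouette-maximizing k is the primary recommendation and the
    Davies-Bouldin-minimizing k the secondary; a disagreement triggers a
    warning carrying both values. Ties go to the smaller k.
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    n = X.shape[0]
    lo, hi = int(k_range[0]), int(k_range[1])
    hi = min(hi, n - 1)
    if lo < 2 or lo > hi:
        raise ValueError(f"k_range must satisfy 2 <= lo <= hi <= n-1, got {k_range}")
    if tree is None:
        tree = ward_linkage(X)
    D = cdist(X, X)
    rows = []
    labels_by_k = {}
    for k in range(lo, hi + 1):
        labels = cut_tree(tree, k)
        labels_by_k[k] = labels
        sil, _ = silhouette(X, labels, dists=D)
        try:
            db = davies_bouldin(X, labels)
        except DegenerateMetricError:
            db = np.nan
        rows.append((k, db, sil))
    crit = pd.DataFrame(rows, columns=["k", "davies_bouldin", "silhouette"])
    k_sil = int(crit.loc[crit["silhouette"].idxmax(), "k"])
    k_db = int(crit.loc[crit["davies_bouldin"].idxmin(), "k"])
    if k_sil != k_db:
        warnings.warn(
            f"cluster-number criteria disagree: silhouette favours k={k_sil}, "
            f"Davies-Bouldin favours k={k_db}; using the silhouette choice",
            stacklevel=2,
        )
    return ClusterSolution(criteria=crit, k_silhouette=k_sil, k_davies_bouldin=k_db,
                           labels=labels_by_k[k_sil], tree=tree)


@dataclass
class SubtypeModel:
    """Frozen subtype definition used by the prodromal classifier.

    ``centroids`` holds one mean globally-scaled voxel profile per
    subtype (rows follow ``subtype_names`` order, which also fixes the
    deterministic tie-break of nearest-centroid assignment);
    ``cn_regional_reference`` holds the control-group mean and SD of
    pons-scaled regional means used by the hypometabolism screen.
    """

    centroids: np.ndarray
    subtype_names: list[str]
    cn_regional_reference: pd.DataFrame | None = None  # index region_id; mean, sd

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.shape[0] != len(self.subtype_names):
            raise ValueError("one centroid per subtype name required")
        means = self.centroids.mean(axis=1)
        if np.any(np.abs(means - 1.0) > 0.01):
            raise ValueError("centroids must be globally scaled (mean ~ 1)")
        if self.cn_regional_reference is not None:
            if (self.cn_regional_reference["sd"] <= 0).any():
                raise ValueError("CN reference SDs must be positive")


def compute_centroids(profiles: np.ndarray, labels: np.ndarray,
                      cn_regional_reference: pd.DataFrame | None = None,
                      names: list[str] | None = None) -> SubtypeModel:
    """Per-cluster voxel-wise mean profiles as a :class:`SubtypeModel`.

    Cluster labels are taken in sorted order; ``names`` (analyst-assigned
    subtype names, e.g. from inspecting the effect-size maps) default to
    ``cluster_<label>``.
    """
    X = np.atleast_2d(np.asarray(profiles, dtype=float))
    groups = _check_labels(X, labels)
    uniq = np.unique(labels)
    centroids = np.array([X[g].mean(axis=0) for g in groups])
    if names is None:
        names = [f"cluster_{u}" for u in uniq]
    if len(names) != len(uniq):
        raise ValueError("need one name per cluster")
    return SubtypeModel(centroids=centroids, subtype_names=list(names),
                        cn_regional_reference=cn_regional_reference)


class SubtypeClustering:
    """Ward subtyping model over globally scaled profiles.

    Parameters
    ----------
    profiles : ProfileSet or ndarray
        Subject x voxel matrix. A :class:`ProfileSet` must carry the
        ``global`` scaling tag; a bare array is checked for row means of 1.

    Examples
    --------
    >>> res = SubtypeClustering(scaled).fit(k_range=(2, 10))
    >>> res.k, res.criteria_agree
    (3, True)
    >>> model = res.to_subtype_model(["limbic_predominant", "typical",
    ...                               "cortical_predominant"], cn_reference)
    """

    def __init__(self, profiles: ProfileSet | np.ndarray,
                 subject_ids: list[str] | None = None):
        if isinstance(profiles, ProfileSet):
            if profiles.scaling != GLOBAL:
                raise ValueError("profiles must be globally scaled before clustering")
            self.X = profiles.X
            self.subject_ids = list(profiles.subject_ids)
        else:
            self.X = np.asarray(profiles, dtype=float)
            if np.any(np.abs(self.X.mean(axis=1) - 1.0) > 1e-6):
                raise ValueError("profiles must be globally scaled (row means = 1); "
                                 "apply preprocess.scale_global first")
            self.subject_ids = subject_ids or [f"S{i:04d}" for i in range(self.X.shape[0])]

    def fit(self, k_range: tuple[int, int] = (2, 10),
            k: int | None = None) -> "SubtypeClusteringResults":
        """Build the Ward tree, evaluate cuts, and return results.

        If ``k`` is given it overrides the criterion-based choice (the
        criteria table is still computed and reported).
        """
        tree = ward_linkage(self.X)
        solution = select_k(self.X, k_range=k_range, tree=tree)
        chosen = int(k) if k is not None else solution.k
        labels = cut_tree(tree, chosen) if k is not None else solution.labels
        return SubtypeClusteringResults(model=self, tree=tree, solution=solution,
                                        k=chosen, labels_=labels)


@dataclass
class SubtypeClusteringResults:
    """Fitted subtyping solution: tree, criteria table, labels, centroids."""

    model: SubtypeClustering
    tree: LinkageTree
    solution: ClusterSolution
    k: int
    labels_: np.ndarray
    _centroid_cache: SubtypeModel | None = field(default=None, repr=False)

    @property
    def criteria(self) -> pd.DataFrame:
        return self.solution.criteria

    @property
    def criteria_agree(self) -> bool:
        return self.solution.criteria_agree

    def cluster_sizes(self) -> pd.Series:
        return pd.Series(self.labels_).value_counts().sort_index()

    def to_subtype_model(self, names: list[str] | None = None,
                         cn_regional_reference: pd.DataFrame | None = None) -> SubtypeModel:
        return compute_centroids(self.model.X, self.labels_,
                                 cn_regional_reference=cn_regional_reference,
                                 names=names)

    def summary(self) -> str:
        sizes = self.cluster_sizes()
        n = self.tree.n_leaves
        lines = [
            "Ward hierarchical subtyping",
            "===========================",
            f"subjects: {n}    voxels: {self.model.X.shape[1]}",
            f"selected k (silhouette): {self.solution.k_silhouette}"
            f"    Davies-Bouldin choice: {self.solution.k_davies_bouldin}"
            + ("" if self.criteria_agree else "    [criteria disagree]"),
            f"reported solution: k = {self.k}",
            "",
            "cluster sizes:",
        ]
        for lab, cnt in sizes.items():
            lines.append(f"  cluster {lab}: n = {cnt} ({100.0 * cnt / n:.1f}%)")
        lines.append("")
        lines.append("criterion values per k:")
        lines.append(self.criteria.to_string(index=False,
                                             float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_dendrogram(self, ax=None):
        """Dendrogram with sqrt(2*dSSE) heights (matplotlib)."""
        from scipy.cluster.hierarchy import dendrogram
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        dendrogram(self.tree.to_scipy(), ax=ax, no_labels=True,
                   color_threshold=0.0)
        ax.set_ylabel("merge height  $\\sqrt{2\\,\\Delta SSE}$")
        return ax
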