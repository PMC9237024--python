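"""Pool per-study PCA loadings, cluster them, and average clusters into RAVs.

A replicable axis of variation (RAV) is the element-wise average of similar
loading vectors observed in independent studies. Loadings are compared by
Spearman correlation distance (1 - rank correlation), clustered by
hierarchical agglomeration with the classic Ward (ward.D) update applied to
the unsquared distances, and the tree is cut at round(P / d) clusters where
P is the number of pooled loadings and d a divisor calibrated so that
synthetic negative controls end up as singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_samples

from .containers import (
    ClusterAssignment,
    ExpressionMatrix,
    NormalizationStats,
    PCResult,
    PooledLoadings,
    RAVIndex,
)
from . import preprocess

__all__ = [
    "compute_cluster_count",
    "pool_loadings",
    "spearman_distance",
    "ward_linkage",
    "ward_cluster",
    "align_and_average",
    "cluster_avg_silhouette",
    "calibrate_d",
    "cluster_census",
    "build_rav_index",
    "DEFAULT_D_GRID",
]

#: Divisor grid swept when calibrating the cluster count.
DEFAULT_D_GRID = (7.0, 6.0, 5.0, 4.0, 3.0, 2.75, 2.5, 2.25, 2.0)


def compute_cluster_count(n_pcs: int, d: float) -> int:
    """Number of clusters requested from the tree cut: round-half-up(n_pcs/d).

    Examples: 10720 pooled PCs at d = 2.25 -> 4764 clusters; 5360 at the
    same d -> 2382.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    if n_pcs < 1:
        raise ValueError("n_pcs must be >= 1")
    return max(1, int(np.floor(n_pcs / d + 0.5)))


def pool_loadings(
    pcs: Sequence[PCResult],
    control_pcs: Sequence[PCResult] = (),
) -> PooledLoadings:
    """Stack per-study loading columns (plus control PC1s) into one matrix.

    Control decompositions contribute only their first PC, mirroring how the
    negative controls are injected into the clustering calibration.
    """
    if not pcs:
        raise ValueError("need at least one PCResult")
    blocks, rows = [], []
    for r in pcs:
        blocks.append(r.loadings)
        for j in range(r.n_components):
            rows.append((r.study_id, j + 1, r.variance_explained[j], False))
    for r in control_pcs:
        blocks.append(r.loadings.iloc[:, :1])
        rows.append((r.study_id, 1, r.variance_explained[0], True))
    loadings = pd.concat(blocks, axis=1, ignore_index=True)
    loadings.columns = range(loadings.shape[1])
    provenance = pd.DataFrame(
        rows, columns=["study_id", "pc", "variance_explained", "is_control"]
    )
    return PooledLoadings(loadings, provenance)


def spearman_distance(pooled: PooledLoadings | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise distance 1 - Spearman rho between pooled loading columns."""
    if isinstance(pooled, PooledLoadings):
        X = pooled.loadings.to_numpy()
    else:
        X = np.asarray(pooled, dtype=np.float64)
    if X.shape[1] < 2:
        raise ValueError("need at least two columns")
    if (X.std(axis=0) == 0).any():
        bad = np.flatnonzero(X.std(axis=0) == 0)[:5].tolist()
        raise ValueError(f"constant columns (rank correlation undefined): {bad}")
    ranks = np.apply_along_axis(rankdata, 0, X)
    rho = np.corrcoef(ranks, rowvar=False)
    dist = 1.0 - rho
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def ward_linkage(dist: np.ndarray) -> np.ndarray:
    """Ward (ward.D) agglomeration on the unsquared input distances.

    The classic Ward update is the Lance-Williams recurrence with Ward
    coefficients applied directly to the supplied dissimilarities. That is
    algebraically identical to running the squared-distance Ward variant on
    the element-wise square roots, so we delegate to scipy's linkage on
    sqrt(dist) and square the merge heights back. Ward on a non-Euclidean
    Spearman distance is a heuristic, but it is the variant this method is
    defined with.
    """
    condensed = squareform(np.asarray(dist, dtype=np.float64), checks=False)
    Z = linkage(np.sqrt(condensed), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return Z


def ward_cluster(dist: np.ndarray, n_clusters: int) -> ClusterAssignment:
    """Cut the ward.D tree at exactly ``n_clusters`` groups.

    Labels are renumbered 1..K contiguously in order of first appearance,
    so the assignment is invariant to internal label bookkeeping.
    """
    P = dist.shape[0]
    if not 1 <= n_clusters <= P:
        raise ValueError(f"n_clusters must be in 1..{P}, got {n_clusters}")
    if n_clusters == P:
        return ClusterAssignment(np.arange(1, P + 1), P)
    Z = ward_linkage(dist)
    raw = cut_tree(Z, n_clusters=n_clusters).ravel()
    _, labels = np.unique(raw, return_inverse=True)
    # renumber by first appearance for determinism across scipy versions
    order = {}
    out = np.empty(P, dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[i] = order[lab]
    return ClusterAssignment(out, n_clusters)


def align_and_average(members: np.ndarray) -> np.ndarray:
    """Sign-align member loadings to the first member and average them.

    PCA loadings are defined up to sign; a member is flipped when its
    Pearson correlation with the reference (first) member is negative, so
    antipodal replicates of the same axis reinforce rather than cancel.
    The average is returned as-is (not re-normalised); downstream use is
    correlation-based and therefore scale-free.
    """
    members = np.asarray(members, dtype=np.float64)
    if members.ndim == 1:
        members = members[:, None]
    if members.shape[1] == 0:
        raise ValueError("need at least one member")
    ref = members[:, 0] - members[:, 0].mean()
    centered = members - members.mean(axis=0, keepdims=True)
    signs = np.where(ref @ centered < 0, -1.0, 1.0)
    return (members * signs).mean(axis=1)


def cluster_avg_silhouette(dist: np.ndarray, assignment: ClusterAssignment) -> pd.Series:
    """Average silhouette width per cluster from a precomputed distance matrix.

    Uses the standard silhouette s(i) = (b - a) / max(a, b); members of
    singleton clusters take width 0 by convention.
    """
    if assignment.n_clusters < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    s = silhouette_samples(dist, assignment.labels, metric="precomputed")
    return pd.Series(s).groupby(assignment.labels).mean().rename("avg_sw")


@dataclass
class CalibrationReport:
    """Outcome of the negative-control d sweep."""

    chosen_d: float | None
    table: pd.DataFrame  # columns: d, n_clusters, n_controls, n_separated, separated


def calibrate_d(
    pooled: PooledLoadings,
    d_grid: Sequence[float] = DEFAULT_D_GRID,
    dist: np.ndarray | None = None,
) -> CalibrationReport:
    """Find the largest divisor d whose cut isolates every negative control.

    For each d (descending, i.e. fewest clusters first) the pooled loadings
    are cut at round(P/d) clusters and we check whether every
    control-flagged column is a singleton cluster. The chosen d is the
    largest one achieving full separation — the minimum number of clusters
    that still separates the controls; ``None`` when no grid value does.
    """
    is_control = pooled.provenance["is_control"].to_numpy()
    if not is_control.any():
        raise ValueError("pooled loadings contain no control-flagged columns")
    if dist is None:
        dist = spearman_distance(pooled)
    P = pooled.n_columns
    rows = []
    chosen = None
    for d in sorted(d_grid, reverse=True):
        K = compute_cluster_count(P, d)
        assignment = ward_cluster(dist, K)
        sizes = np.bincount(assignment.labels)[1:]
        singleton = sizes[assignment.labels[is_control] - 1] == 1
        n_sep = int(singleton.sum())
        full = bool(singleton.all())
        rows.append((d, K, int(is_control.sum()), n_sep, full))
        if full and chosen is None:
            chosen = d
    table = pd.DataFrame(
        rows, columns=["d", "n_clusters", "n_controls", "n_separated", "separated"]
    )
    if chosen is None:
        warnings.warn("no divisor in the grid separates all negative controls")
    return CalibrationReport(chosen, table)


def cluster_census(
    total_pcs: int,
    n_clusters: int,
    n_single_element: int,
    n_two_element: int,
) -> dict[str, float]:
    """Summary statistics of a cluster size census.

    From the total number of pooled PCs, the number of clusters, and the
    counts of one- and two-element clusters, derive the number of
    multi-element clusters, their mean size, and the percentage of
    multi-element clusters that have exactly two members.
    """
    if not 0 <= n_single_element <= n_clusters:
        raise ValueError("singleton count out of range")
    multi = n_clusters - n_single_element
    if multi <= 0:
        raise ValueError("no multi-element clusters")
    return {
        "total_pcs": float(total_pcs),
        "n_multi_element": float(multi),
        "mean_multi_element_size": (total_pcs - n_single_element) / multi,
        "two_element_pct": 100.0 * n_two_element / multi,
    }


@dataclass
class BuildResult:
    """Everything produced by one index build."""

    index: RAVIndex
    stats: NormalizationStats
    pooled: PooledLoadings
    assignment: ClusterAssignment
    genes: pd.Index
    dropped_genes: list[str]


def build_rav_index(
    studies: Sequence[ExpressionMatrix],
    n_pcs: int = 20,
    d: float = 2.25,
    variance_quantile: float = 0.90,
    n_clusters: int | None = None,
    controls: Sequence[ExpressionMatrix] | None = None,
    keep_distance: bool = False,
) -> BuildResult:
    """Run the full index build: preprocess, per-study PCA, pool, cluster, average.

    Steps: per-study top-variable-gene selection at ``variance_quantile``,
    lexicographically ordered intersection of the gene lists, pooled row
    normalisation over all samples, per-study PCA of the top ``n_pcs``
    loadings, Spearman distance, ward.D clustering at
    ``n_clusters or round(P/d)``, then sign-aligned averaging per cluster.

    ``controls`` are pre-normalised matrices (e.g. from
    :func:`ravkit.synthetic.make_negative_controls`) whose PC1s join the
    pool flagged as controls; they participate in clustering but their
    columns are excluded from no step — flags are carried in provenance.
    """
    if len(studies) < 2:
        raise ValueError("need at least two studies to build an index")
    gene_lists = [preprocess.top_variable_genes(s, variance_quantile) for s in studies]
    genes = preprocess.common_genes(gene_lists)
    normalized, stats, dropped = preprocess.pooled_row_normalize(studies, genes)
    pcs = [preprocess.dataset_pca(s, n_pcs) for s in normalized]
    control_pcs = []
    if controls:
        control_pcs = [preprocess.dataset_pca(c.restrict(stats.gene_ids), n_pcs=1) for c in controls]
    pooled = pool_loadings(pcs, control_pcs)
    dist = spearman_distance(pooled)
    K = n_clusters if n_clusters is not None else compute_cluster_count(pooled.n_columns, d)
    assignment = ward_cluster(dist, K)
    sw = (
        cluster_avg_silhouette(dist, assignment)
        if K >= 2
        else pd.Series({1: 0.0}, name="avg_sw")
    )

    X = pooled.loadings.to_numpy()
    rav_names = [f"RAV{k}" for k in range(1, K + 1)]
    ravs = np.empty((X.shape[0], K))
    info_rows = []
    prov = pooled.provenance.copy()
    prov["rav"] = [f"RAV{l}" for l in assignment.labels]
    for k in range(1, K + 1):
        idx = assignment.members(k)
        ravs[:, k - 1] = align_and_average(X[:, idx])
        info_rows.append(
            (
                len(idx),
                float(sw.get(k, 0.0)),
                float(prov.iloc[idx]["variance_explained"].mean()),
            )
        )
    index = RAVIndex(
        ravs=pd.DataFrame(ravs, index=pooled.gene_ids, columns=rav_names),
        cluster_info=pd.DataFrame(
            info_rows, index=pd.Index(rav_names, name="rav"),
            columns=["size", "avg_sw", "mean_var_explained"],
        ),
        provenance=prov,
    )
    result = BuildResult(index, stats, pooled, assignment, pd.Index(genes), dropped)
    if keep_distance:
        result.distance = dist  # type: ignore[attr-defined]
    return result
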