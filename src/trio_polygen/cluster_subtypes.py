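"""Transmission-deviation clustering and diagnostic enrichment.

Trios are clustered on their standardized pTDT deviation profiles with
Ward's minimum-variance method on Euclidean distances. The cluster count is
chosen by majority vote of three internal validity indices (connectivity,
mean silhouette width, Dunn index) over a candidate range; observations with
negative silhouette width are pruned; and over-representation of a
diagnostic subgroup in a cluster is tested with Fisher's exact test
(minimum-likelihood two-sided rule) with an exact conditional odds-ratio
confidence interval, the sample odds ratio reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.spatial.distance import squareform, pdist
from scipy.stats import fisher_exact, nchypergeom_fisher
from sklearn.cluster import KMeans

from trio_polygen.genetics_io import TrioSet
from trio_polygen.ptdt_stats import DeviationMatrix

logger = logging.getLogger("trio_polygen")

DUNN_SENTINEL = 1e12  # stands in for an infinite Dunn index (zero diameter)


class ClusteringError(ValueError):
    """The clustering request is undefined on the given data."""


@dataclass
class ClusterAssignment:
    """Cluster labels with per-observation silhouette widths.

    ``retained`` is silhouette >= 0; labels are contiguous from 1 in order
    of first appearance.
    """

    trio_ids: list[str]
    labels: np.ndarray
    silhouette: np.ndarray
    retained: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"CHILD": self.trio_ids, "CLUSTER": self.labels,
             "SILHOUETTE": self.silhouette, "RETAINED": self.retained}
        )

    def cluster_sizes(self, retained_only: bool = False) -> dict[int, int]:
        mask = self.retained if retained_only else np.ones(len(self.labels), bool)
        vals, counts = np.unique(self.labels[mask], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class ValidityIndices:
    connectivity: float
    silhouette: float
    dunn: float


@dataclass
class EnrichmentResult:
    """Fisher 2x2 enrichment of a subgroup across two clusters."""

    table: np.ndarray  # [[in-cluster & subgroup, in-cluster & other], [out & subgroup, out & other]]
    odds_ratio: float  # sample OR (a*d)/(b*c)
    conditional_or: float  # conditional maximum-likelihood OR
    ci_low: float
    ci_high: float
    p: float


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def ward_cluster(deviations: DeviationMatrix | np.ndarray, k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering into k groups (labels 1..k)."""
    X = deviations.values if isinstance(deviations, DeviationMatrix) else np.asarray(deviations, float)
    if k < 2:
        raise ClusteringError("k must be >= 2")
    if k > X.shape[0]:
        raise ClusteringError(f"k={k} exceeds the {X.shape[0]} observations")
    Z = linkage(X, method="ward")
    return _relabel_contiguous(fcluster(Z, t=k, criterion="maxclust"))


def silhouette_widths(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-observation silhouette s(i) = (b - a) / max(a, b) from Euclidean
    distances; for a singleton cluster a(i) is defined as 0 (so s(i) relies
    on the nearest other cluster alone)."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ClusteringError("silhouette is undefined with a single cluster")
    D = squareform(pdist(np.asarray(X, float)))
    n = len(labels)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        a = D[i, own[own != i]].mean() if own.size > 1 else 0.0
        b = min(D[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def validity_indices(X: np.ndarray, labels: np.ndarray,
                     neighborhood: int = 10) -> ValidityIndices:
    """Connectivity, mean silhouette width, and Dunn index for a partition.

    Connectivity sums, over each observation's ``neighborhood`` nearest
    neighbors, 1/rank for every neighbor assigned to a different cluster
    (lower is better). Dunn is the smallest between-cluster distance over
    the largest within-cluster diameter (higher is better); a zero diameter
    maps to a large finite sentinel.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ClusteringError("validity indices need >= 2 clusters")
    for c in uniq:
        if not (labels == c).any():
            raise ClusteringError(f"empty cluster {c}")
    n = X.shape[0]
    D = squareform(pdist(X))
    L = min(neighborhood, n - 1)

    conn = 0.0
    order = np.argsort(D + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    for i in range(n):
        for rank, j in enumerate(order[i, :L], start=1):
            if labels[j] != labels[i]:
                conn += 1.0 / rank

    sil = float(silhouette_widths(X, labels).mean())

    inter = np.inf
    intra = 0.0
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for c in uniq:
        m = members[c]
        if m.size > 1:
            intra = max(intra, float(D[np.ix_(m, m)].max()))
    for a_i, c1 in enumerate(uniq):
        for c2 in uniq[a_i + 1:]:
            inter = min(inter, float(D[np.ix_(members[c1], members[c2])].min()))
    dunn = DUNN_SENTINEL if intra == 0 else min(inter / intra, DUNN_SENTINEL)
    return ValidityIndices(connectivity=conn, silhouette=sil, dunn=dunn)


def choose_k(deviations: DeviationMatrix | np.ndarray, k_range=range(2, 7),
             methods: tuple[str, ...] = ("ward",), neighborhood: int = 10,
             seed: int = 0) -> tuple[int, pd.DataFrame]:
    """Pick the cluster count by majority vote of the validity indices.

    Each (method, index) combination votes for its best k (min connectivity;
    max silhouette; max Dunn); the k with most votes wins, ties toward the
    smaller k. The full per-k index table is returned for audit.
    """
    X = deviations.values if isinstance(deviations, DeviationMatrix) else np.asarray(deviations, float)
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ClusteringError("empty k range")
    if k_range[0] < 2 or k_range[-1] > X.shape[0] - 1:
        raise ClusteringError(f"k range must lie in [2, {X.shape[0] - 1}]")
    rows = []
    for method in methods:
        for k in k_range:
            if method == "ward":
                labels = ward_cluster(X, k)
            elif method == "kmeans":
                labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X) + 1
            else:
                raise ClusteringError(f"unknown clustering method {method!r}")
            v = validity_indices(X, labels, neighborhood=neighborhood)
            rows.append((method, k, v.connectivity, v.silhouette, v.dunn))
    table = pd.DataFrame(rows, columns=["method", "k", "connectivity", "silhouette", "dunn"])

    votes: dict[int, int] = {k: 0 for k in k_range}
    for method in methods:
        sub = table[table["method"] == method].set_index("k")
        votes[int(sub["connectivity"].idxmin())] += 1
        votes[int(sub["silhouette"].idxmax())] += 1
        votes[int(sub["dunn"].idxmax())] += 1
    best = max(k_range, key=lambda k: (votes[k], -k))
    return best, table


def silhouette_prune(deviations: DeviationMatrix | np.ndarray, labels: np.ndarray,
                     trio_ids: list[str] | None = None) -> ClusterAssignment:
    """Flag observations with negative silhouette width as not retained."""
    X = deviations.values if isinstance(deviations, DeviationMatrix) else np.asarray(deviations, float)
    ids = (deviations.trio_ids if isinstance(deviations, DeviationMatrix) and trio_ids is None
           else trio_ids or [str(i) for i in range(X.shape[0])])
    sil = silhouette_widths(X, labels)
    retained = sil >= 0
    if not retained.any():
        raise ClusteringError("silhouette pruning removed every observation")
    logger.info("silhouette_prune: removed %d of %d observations",
                int((~retained).sum()), len(retained))
    return ClusterAssignment(trio_ids=list(ids), labels=np.asarray(labels),
                             silhouette=sil, retained=retained)


def fisher_exact_ci(table: np.ndarray, alpha: float = 0.05) -> tuple[float, float]:
    """Exact conditional (noncentral hypergeometric) CI for the odds ratio."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    M, ntag, nsamp = a + b + c + d, a + c, a + b
    lo_support = max(0, nsamp - (M - ntag))
    hi_support = min(ntag, nsamp)

    def sf_at(log_psi: float) -> float:  # P(X >= a | psi)
        dist = nchypergeom_fisher(M, ntag, nsamp, np.exp(log_psi))
        return float(dist.sf(a - 1))

    def cdf_at(log_psi: float) -> float:  # P(X <= a | psi)
        dist = nchypergeom_fisher(M, ntag, nsamp, np.exp(log_psi))
        return float(dist.cdf(a))

    if a == lo_support:
        lower = 0.0
    else:
        lower = float(np.exp(brentq(lambda lp: sf_at(lp) - alpha / 2, -50, 50)))
    if a == hi_support:
        upper = float("inf")
    else:
        upper = float(np.exp(brentq(lambda lp: cdf_at(lp) - alpha / 2, -50, 50)))
    return lower, upper


def _conditional_mle_or(table: np.ndarray) -> float:
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    M, ntag, nsamp = a + b + c + d, a + c, a + b
    lo = max(0, nsamp - (M - ntag))
    hi = min(ntag, nsamp)
    if a == lo:
        return 0.0
    if a == hi:
        return float("inf")
    from scipy.optimize import minimize_scalar

    def neg_logpmf(log_psi: float) -> float:
        return -nchypergeom_fisher(M, ntag, nsamp, np.exp(log_psi)).logpmf(a)

    res = minimize_scalar(neg_logpmf, bounds=(-30, 30), method="bounded")
    return float(np.exp(res.x))


def enrichment_test(table_or_assignment, trios: TrioSet | None = None,
                    subgroup: str = "AS", cluster: int | None = None) -> EnrichmentResult:
    """Fisher exact enrichment of a subgroup in one cluster vs the rest.

    Accepts either an explicit 2x2 table ``[[a, b], [c, d]]`` (rows =
    cluster / other cluster, columns = subgroup / other) or a pruned
    :class:`ClusterAssignment` plus the trio labels; in the latter case the
    tested cluster defaults to the one with the higher subgroup proportion.
    Two-tailed p follows the minimum-likelihood rule; the CI is the exact
    conditional interval.
    """
    if isinstance(table_or_assignment, ClusterAssignment):
        assignment = table_or_assignment
        if trios is None:
            raise ClusteringError("trio labels are required with an assignment")
        label_map = dict(zip(trios.table["CHILD"], trios.table["LABEL"]))
        mask = assignment.retained
        labels = assignment.labels[mask]
        is_sub = np.array([label_map.get(i) == subgroup
                           for i in np.asarray(assignment.trio_ids)[mask]])
        uniq = np.unique(labels)
        if uniq.size != 2:
            raise ClusteringError(f"enrichment test needs exactly 2 retained clusters, got {uniq.size}")
        if cluster is None:
            props = {c: is_sub[labels == c].mean() for c in uniq}
            cluster = max(uniq, key=lambda c: props[c])
        inc = labels == cluster
        table = np.array([
            [int((inc & is_sub).sum()), int((inc & ~is_sub).sum())],
            [int((~inc & is_sub).sum()), int((~inc & ~is_sub).sum())],
        ])
    else:
        table = np.asarray(table_or_assignment, dtype=int)
        if table.shape != (2, 2) or (table < 0).any():
            raise ClusteringError("enrichment table must be 2x2 and non-negative")

    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ClusteringError("enrichment test undefined with a zero margin")
    a, b = table[0]
    c, d = table[1]
    sample_or = float("inf") if b * c == 0 else (a * d) / (b * c)
    p = float(fisher_exact(table, alternative="two-sided").pvalue)
    lo, hi = fisher_exact_ci(table)
    return EnrichmentResult(table=table, odds_ratio=sample_or,
                            conditional_or=_conditional_mle_or(table),
                            ci_low=lo, ci_high=hi, p=p)
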