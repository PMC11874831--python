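"""Comorbidity pattern discovery via correlation-distance clustering.

The entities clustered are CONDITIONS (binary indicator columns), not
patients: the reported comorbidity patterns are groupings of conditions that
tend to co-occur across patients. Rare conditions are dropped first, the
remaining indicator columns are z-scored (a no-op for Pearson correlation,
retained for fidelity to the standardize-then-correlate description), the
pairwise distance is ``d = 1 - r`` (optionally ``sqrt(2 (1 - r))``), and a
bottom-up agglomeration implemented here from first principles — repeatedly
merging the closest pair under the configured linkage, with Lance-Williams
distance updates — produces the dendrogram. Cutting the tree yields condition
clusters; patients are then assigned to the cluster whose conditions they
all carry.

Determinism: ties on the merge distance are broken by the lexicographically
smallest pair of cluster labels, a cluster's label being its alphabetically
first member condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("oncoburden.clustering")

__all__ = [
    "Dendrogram",
    "ConditionCluster",
    "ConditionClusterSet",
    "filter_rare_conditions",
    "correlation_distance",
    "agglomerative_cluster",
    "extract_clusters",
    "assign_patients",
    "CorrelationHierarchicalClustering",
]

LINKAGES = ("average", "complete", "single")


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: the two merged groups (as sorted tuples of
    leaf labels) and the inter-group distance at which they merged."""

    left: tuple[str, ...]
    right: tuple[str, ...]
    height: float

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class Dendrogram:
    """Ordered merge list over condition leaves."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]
    linkage: str = "average"

    def __post_init__(self) -> None:
        if len(self.merges) != max(len(self.leaves) - 1, 0):
            raise ValueError("a dendrogram over k leaves needs k-1 merges")
        if any(m.height < -1e-12 for m in self.merges):
            raise ValueError("merge heights must be non-negative")

    def cut(self, n_clusters: int | None = None,
            height: float | None = None) -> list[tuple[str, ...]]:
        """Groups after cutting the tree.

        Either keep merging until ``n_clusters`` groups remain, or apply all
        merges with height <= ``height`` (so a cut at 0 leaves every leaf in
        its own group for strictly positive heights).
        """
        if (n_clusters is None) == (height is None):
            raise ValueError("specify exactly one of n_clusters or height")
        groups: list[set[str]] = [{leaf} for leaf in self.leaves]

        def apply(merge: Merge) -> None:
            li = next(i for i, g in enumerate(groups) if set(merge.left) <= g)
            ri = next(i for i, g in enumerate(groups) if set(merge.right) <= g)
            groups[li] = groups[li] | groups[ri]
            del groups[ri]

        if n_clusters is not None:
            if not 1 <= n_clusters <= len(self.leaves):
                raise ValueError(
                    f"n_clusters must lie in 1..{len(self.leaves)}")
            for merge in self.merges[: len(self.leaves) - n_clusters]:
                apply(merge)
        else:
            for merge in self.merges:
                if merge.height <= height:
                    apply(merge)
        return [tuple(sorted(g)) for g in
                sorted(groups, key=lambda g: sorted(g)[0])]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (a leaf's
        branch length is half the height of the merge that absorbs it)."""
        node: dict[tuple[str, ...], str] = {}
        node_h: dict[tuple[str, ...], float] = {}
        for leaf in self.leaves:
            node[(leaf,)] = leaf
            node_h[(leaf,)] = 0.0
        for m in self.merges:
            l, r = tuple(sorted(m.left)), tuple(sorted(m.right))
            bl_l = max(m.height / 2.0 - node_h[l], 0.0)
            bl_r = max(m.height / 2.0 - node_h[r], 0.0)
            key = m.members
            node[key] = f"({node[l]}:{bl_l:.6g},{node[r]}:{bl_r:.6g})"
            node_h[key] = m.height / 2.0
            del node[l], node[r]
        (root,) = node.values()
        return root + ";"

    def to_merge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"step": i + 1,
              "left": "+".join(m.left),
              "right": "+".join(m.right),
              "height": m.height} for i, m in enumerate(self.merges)])


@dataclass(frozen=True)
class ConditionCluster:
    conditions: tuple[str, ...]
    patient_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass
class ConditionClusterSet:
    """Extracted comorbidity clusters (>=2 conditions each) with members."""

    clusters: list[ConditionCluster] = field(default_factory=list)
    stratum: str = ""
    linkage: str = "average"
    singletons: tuple[str, ...] = ()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stratum": self.stratum,
              "cluster": "-".join(c.conditions),
              "n_conditions": len(c.conditions),
              "n_patients": c.n} for c in self.clusters])


def filter_rare_conditions(matrix: pd.DataFrame, min_count: int = 3) -> pd.DataFrame:
    """Drop condition columns with fewer than ``min_count`` positives."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = matrix.sum(axis=0)
    dropped = [c for c in matrix.columns if counts[c] < min_count]
    for c in dropped:
        logger.info("dropping rare condition %s (n=%d < %d)",
                    c, int(counts[c]), min_count)
    kept = matrix.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("no conditions remain after rare-condition filtering")
    return kept


def correlation_distance(matrix: pd.DataFrame,
                         transform: str = "one_minus_r") -> pd.DataFrame:
    """Pairwise distance between condition columns.

    ``d = 1 - r`` (default) or ``d = sqrt(2 (1 - r))``, with ``r`` the
    Pearson correlation of the indicator columns across patients. Columns
    are z-scored first (which leaves ``r`` unchanged). A zero-variance
    column is an error: it should have been removed by the rare-condition
    filter.
    """
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero = [c for c, s in zip(matrix.columns, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance condition column(s): {zero}")
    Z = (X - X.mean(axis=0)) / sd
    r = np.clip((Z.T @ Z) / X.shape[0], -1.0, 1.0)
    if transform == "one_minus_r":
        d = 1.0 - r
    elif transform == "sqrt":
        d = np.sqrt(np.maximum(2.0 * (1.0 - r), 0.0))
    else:
        raise ValueError(f"unknown distance transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def _validate_distances(distances: pd.DataFrame) -> None:
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")


def agglomerative_cluster(distances: pd.DataFrame,
                          linkage: str = "average") -> Dendrogram:
    """Bottom-up agglomeration with Lance-Williams distance updates.

    Starts from singleton clusters and repeatedly merges the pair at minimum
    inter-cluster distance under the chosen linkage (average, complete or
    single), recording merge heights. Ties are broken by the
    lexicographically smallest pair of cluster labels.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    _validate_distances(distances)
    labels = [str(c) for c in distances.columns]
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves to cluster")

    clusters: dict[str, tuple[str, ...]] = {lab: (lab,) for lab in labels}
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            dist[frozenset((a, b))] = float(distances.loc[a, b])

    merges: list[Merge] = []
    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        for key, d in dist.items():
            a, b = sorted(key)
            cand = (d, a, b)
            if best is None or cand < best:
                best = cand
        d_min, a, b = best  # type: ignore[misc]
        merges.append(Merge(left=clusters[a], right=clusters[b], height=d_min))
        new_label = min(a, b)  # label = alphabetically first member
        old = max(a, b)
        for other in list(clusters):
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            if linkage == "average":
                na, nb = sizes[a], sizes[b]
                d_new = (na * da + nb * db) / (na + nb)
            elif linkage == "complete":
                d_new = max(da, db)
            else:
                d_new = min(da, db)
            dist[frozenset((new_label, other))] = d_new
        dist.pop(frozenset((a, b)))
        clusters[new_label] = tuple(sorted(clusters[a] + clusters[b]))
        sizes[new_label] = sizes[a] + sizes[b]
        if old != new_label:
            del clusters[old], sizes[old]
    return Dendrogram(leaves=tuple(labels), merges=tuple(merges),
                      linkage=linkage)


def extract_clusters(tree: Dendrogram, n_clusters: int | None = None,
                     height: float | None = None) -> list[tuple[str, ...]]:
    """Cut the dendrogram; groups with >=2 conditions are the clusters,
    singleton groups are reported by the caller but not promoted."""
    return tree.cut(n_clusters=n_clusters, height=height)


def assign_patients(clusters: Sequence[Sequence[str]], matrix: pd.DataFrame,
                    exclusive: bool = True,
                    stratum: str = "", linkage: str = "average") -> ConditionClusterSet:
    """Assign patients to condition clusters.

    A patient belongs to a cluster iff all of its conditions are positive.
    Under ``exclusive`` (default) a patient matching several clusters is
    assigned to the one with most matched conditions, ties broken by earlier
    cluster order; with ``exclusive=False`` multi-membership is allowed.
    Singleton groups are recorded but not promoted to clusters.
    """
    multi = [tuple(c) for c in clusters if len(c) >= 2]
    singles = tuple(c[0] for c in clusters if len(c) == 1)
    seen: set[str] = set()
    for c in multi:
        if seen & set(c):
            raise ValueError("cluster condition sets overlap")
        seen |= set(c)
    match = {c: (matrix[list(c)].to_numpy(dtype=int) == 1).all(axis=1)
             for c in multi}
    ids = matrix.index.to_numpy()
    if exclusive and len(multi) > 1:
        order = sorted(range(len(multi)),
                       key=lambda i: (-len(multi[i]), i))
        taken = np.zeros(len(matrix), dtype=bool)
        resolved = {}
        n_conflicts = 0
        for i in order:
            c = multi[i]
            m = match[c] & ~taken
            n_conflicts += int((match[c] & taken).sum())
            resolved[c] = m
            taken |= m
        if n_conflicts:
            logger.info("%d multi-cluster patients assigned exclusively "
                        "(largest cluster wins, earlier order breaks ties)",
                        n_conflicts)
        match = resolved
    out = [ConditionCluster(conditions=c,
                            patient_ids=tuple(ids[match[c]].tolist()))
           for c in multi]
    return ConditionClusterSet(clusters=out, stratum=stratum,
                               linkage=linkage, singletons=singles)


class CorrelationHierarchicalClustering(BaseEstimator):
    """Condition clustering estimator.

    Parameters
    ----------
    linkage : {"average", "complete", "single"}
    distance : {"one_minus_r", "sqrt"}
        Transform from Pearson correlation to distance.
    min_count : int
        Rare-condition threshold (columns with fewer positives are dropped
        before clustering).
    n_clusters : int or None, height : float or None
        Tree-cut rule; exactly one must be set for :meth:`fit` to populate
        cluster assignments (``n_clusters`` wins when both given).
    exclusive : bool
        Exclusive patient-to-cluster assignment.

    Attributes (after ``fit(X)`` with X a patients x conditions 0/1 frame)
    ----------
    kept_conditions_ : columns surviving the rare filter
    distances_ : condition-condition distance matrix
    dendrogram_ : :class:`Dendrogram`
    cluster_conditions_ : list of condition tuples (>=2 members)
    cluster_set_ : :class:`ConditionClusterSet`
    labels_ : per-patient cluster label ("-".joined conditions) or "none"
    """

    def __init__(self, linkage: str = "average", distance: str = "one_minus_r",
                 min_count: int = 3, n_clusters: int | None = 2,
                 height: float | None = None, exclusive: bool = True):
        self.linkage = linkage
        self.distance = distance
        self.min_count = min_count
        self.n_clusters = n_clusters
        self.height = height
        self.exclusive = exclusive

    def fit(self, X: pd.DataFrame, y=None) -> "CorrelationHierarchicalClustering":
        matrix = filter_rare_conditions(X, min_count=self.min_count)
        self.kept_conditions_ = list(matrix.columns)
        self.distances_ = correlation_distance(matrix, transform=self.distance)
        self.dendrogram_ = agglomerative_cluster(self.distances_,
                                                 linkage=self.linkage)
        if self.n_clusters is not None:
            groups = self.dendrogram_.cut(n_clusters=self.n_clusters)
        else:
            groups = self.dendrogram_.cut(height=self.height)
        self.groups_ = groups
        self.cluster_conditions_ = [g for g in groups if len(g) >= 2]
        self.cluster_set_ = assign_patients(
            groups, matrix, exclusive=self.exclusive, linkage=self.linkage)
        labels = pd.Series("none", index=X.index, dtype=object)
        for cluster in self.cluster_set_.clusters:
            labels.loc[list(cluster.patient_ids)] = "-".join(cluster.conditions)
        self.labels_ = labels
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
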