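"""Gene cluster family (GCF) calling and dendrograms.

Families are called by density clustering (DBSCAN) on the distance
``1 - score`` at an epsilon of 0.55 — i.e. cluster pairs scoring at least
0.45 are neighbors.  With the default ``min_members = 2`` this is exactly
the connected components of the threshold graph: subgraphs of the cluster
network are the families, and isolated clusters are singletons.

UPGMA (average-linkage agglomerative clustering) over the same distance
yields ultrametric dendrograms of the cluster set or of single families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .similarity import SimilarityEdge, SimilarityResult

__all__ = [
    "Dendrogram",
    "GCFAssignment",
    "GCFClusterer",
    "to_distance",
    "call_families",
    "network_edges",
    "edges_to_score_matrix",
    "upgma",
]

SINGLETON = "singleton"


def to_distance(score: float) -> float:
    """Convert a similarity score in [0, 1] to the distance ``1 - score``."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score outside [0, 1]: {score}")
    return 1.0 - score


def _as_square(dist, ids=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        if ids is None:
            ids = [str(i) for i in dist.index]
        dist = dist.to_numpy(dtype=float)
    else:
        dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError(f"distance matrix must be square, got {dist.shape}")
    if ids is None:
        ids = [str(i) for i in range(dist.shape[0])]
    if len(ids) != dist.shape[0]:
        raise ValueError("ids length does not match matrix size")
    return dist, list(ids)


def _check_distance(dist: np.ndarray) -> None:
    if np.isnan(dist).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")


@dataclass
class GCFAssignment:
    """Cluster → family assignment.

    ``assignments`` maps every input cluster id either to a contiguous
    integer family label (0, 1, ...) or to ``None`` for singletons (DBSCAN
    noise).  Families have at least ``min_members`` members.
    """

    assignments: dict[str, int | None]
    epsilon: float
    min_members: int

    @property
    def n_families(self) -> int:
        labels = {v for v in self.assignments.values() if v is not None}
        return len(labels)

    @property
    def singletons(self) -> list[str]:
        return [k for k, v in self.assignments.items() if v is None]

    def families(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for cid, lab in self.assignments.items():
            if lab is not None:
                out.setdefault(lab, []).append(cid)
        return out

    def to_labels(self, ids: list[str] | None = None) -> list[int]:
        """Integer labels suitable for partition comparison (e.g. ARI).

        Each singleton gets its own fresh label so that two assignments
        agreeing on families *and* on singleton status compare as the same
        partition.
        """
        ids = ids if ids is not None else list(self.assignments)
        next_free = (
            max((v for v in self.assignments.values() if v is not None), default=-1)
            + 1
        )
        labels = []
        for cid in ids:
            lab = self.assignments[cid]
            if lab is None:
                lab = next_free
                next_free += 1
            labels.append(lab)
        return labels

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (cid, SINGLETON if lab is None else lab)
            for cid, lab in self.assignments.items()
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "family_id"])


class GCFClusterer(ClusterMixin, BaseEstimator):
    """Density-based gene-cluster-family caller (sklearn estimator).

    Wraps DBSCAN on a precomputed matrix.  The neighborhood is inclusive
    (``d <= epsilon``); with ``min_members = 2`` the clustering equals
    connected components of the epsilon-threshold graph and noise points
    are the singletons.

    Parameters
    ----------
    epsilon:
        Neighborhood radius on the distance scale (default 0.55, i.e. a
        similarity score of 0.45).
    min_members:
        DBSCAN ``min_samples``; also the minimum family size.
    input:
        ``"distance"`` (default) if ``X`` is already ``1 - score``;
        ``"similarity"`` to convert a score matrix internally, allowing
        composition after :class:`~gcfkit.similarity.BGCSimilarity`.

    Attributes
    ----------
    labels_:
        Contiguous integer family labels in first-appearance order;
        singletons are ``-1``.
    assignment_:
        The corresponding :class:`GCFAssignment` (ids taken from the
        DataFrame index when ``X`` is a DataFrame).
    """

    def __init__(
        self, epsilon: float = 0.55, min_members: int = 2, input: str = "distance"
    ) -> None:
        self.epsilon = epsilon
        self.min_members = min_members
        self.input = input

    def fit(self, X, y=None) -> "GCFClusterer":
        if self.input not in ("distance", "similarity"):
            raise ValueError(f"unknown input kind: {self.input!r}")
        mat, ids = _as_square(X)
        if self.input == "similarity":
            mat = 1.0 - mat
            np.fill_diagonal(mat, 0.0)
        _check_distance(mat)
        raw = DBSCAN(
            eps=self.epsilon, min_samples=self.min_members, metric="precomputed"
        ).fit_predict(mat)
        # relabel contiguously in order of first appearance
        remap: dict[int, int] = {}
        labels = np.empty_like(raw)
        for i, lab in enumerate(raw):
            if lab == -1:
                labels[i] = -1
            else:
                if lab not in remap:
                    remap[lab] = len(remap)
                labels[i] = remap[lab]
        self.labels_ = labels
        self.assignment_ = GCFAssignment(
            assignments={
                cid: (None if lab == -1 else int(lab))
                for cid, lab in zip(ids, labels)
            },
            epsilon=self.epsilon,
            min_members=self.min_members,
        )
        return self


def call_families(
    dist,
    epsilon: float = 0.55,
    min_members: int = 2,
    ids: list[str] | None = None,
) -> GCFAssignment:
    """Call gene cluster families from a symmetric distance matrix."""
    mat, ids = _as_square(dist, ids)
    est = GCFClusterer(epsilon=epsilon, min_members=min_members).fit(
        pd.DataFrame(mat, index=ids, columns=ids)
    )
    return est.assignment_


def network_edges(
    result: SimilarityResult, score_threshold: float = 0.45
) -> list[tuple[str, str, float]]:
    """Edges of the cluster network: pairs scoring at or above the threshold."""
    return [
        (e.cluster_a, e.cluster_b, e.score)
        for e in result.edges
        if e.score >= score_threshold
    ]


def edges_to_score_matrix(edges: list[SimilarityEdge]) -> pd.DataFrame:
    """Rebuild the symmetric score matrix (unit diagonal) from an edge list."""
    ids = sorted({e.cluster_a for e in edges} | {e.cluster_b for e in edges})
    idx = {cid: i for i, cid in enumerate(ids)}
    mat = np.eye(len(ids))
    for e in edges:
        i, j = idx[e.cluster_a], idx[e.cluster_b]
        mat[i, j] = mat[j, i] = e.score
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class Dendrogram:
    """A node of an ultrametric merge tree (UPGMA output).

    Leaves carry a ``name`` and height 0; internal nodes carry the merge
    height (half the merge distance) and exactly two children.  Branch
    lengths in Newick output are parent height minus child height.
    """

    height: float
    name: str | None = None
    children: tuple["Dendrogram", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return _newick(self) + ";"


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def _newick(node: Dendrogram) -> str:
    if node.is_leaf:
        return node.name or ""
    parts = [
        f"{_newick(c)}:{_fmt(node.height - c.height)}" for c in node.children
    ]
    return "(" + ",".join(parts) + ")"


def upgma(dist, ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    Iteratively merges the closest pair of active nodes; the new node's
    height is half the merge distance and its distance to every other node
    is the size-weighted average of its children's distances.  Ties are
    broken deterministically by the lexicographically smallest leaf label
    contained in each candidate node.
    """
    mat, ids = _as_square(dist, ids)
    _check_distance(mat)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("UPGMA needs at least two leaves")

    nodes: dict[int, Dendrogram] = {
        i: Dendrogram(height=0.0, name=ids[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: ids[i] for i in range(n)}  # smallest leaf label per node
    d = {
        (i, j): float(mat[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        best = min(
            d.items(),
            key=lambda kv: (
                kv[1],
                min(keys[kv[0][0]], keys[kv[0][1]]),
                max(keys[kv[0][0]], keys[kv[0][1]]),
            ),
        )
        (i, j), dij = best
        height = dij / 2.0
        first, second = (i, j) if keys[i] <= keys[j] else (j, i)
        merged = Dendrogram(height=height, children=(nodes[first], nodes[second]))
        ni, nj = sizes[i], sizes[j]
        new_d = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new_d[k] = (ni * dik + nj * djk) / (ni + nj)
        for key in list(d):
            if i in key or j in key:
                del d[key]
        del nodes[i], nodes[j], sizes[i], sizes[j], keys[i], keys[j]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        keys[next_id] = min(merged.leaves())
        for k, val in new_d.items():
            d[(min(k, next_id), max(k, next_id))] = val
        next_id += 1
    return next(iter(nodes.values()))
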