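"""Pairwise BGC similarity: backbone identity, domain-content Jaccard, and
the weighted combined score.

Two gene clusters are compared on two axes:

* **sequence identity** — the median pairwise identity of their shared
  backbone-enzyme domains (adenylation, condensation, thiolation, KS, AT,
  DMAT, TE), computed from deterministic global alignments;
* **Jaccard similarity** — |A ∩ B| / |A ∪ B| of their protein-domain sets.

The combined score is the weighted sum ``0.8 * identity + 0.2 * jaccard``
by default, so backbone relatedness dominates while shared tailoring-domain
content still contributes.  Scores live in [0, 1]; ``1 - score`` is the
distance used downstream for family calling and dendrograms.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, TransformerMixin

from .records import AMINO_ACIDS, ClusterRecord

__all__ = [
    "DEFAULT_BACKBONE_TYPES",
    "AlignmentParams",
    "ScoreWeights",
    "SimilarityEdge",
    "SimilarityResult",
    "global_align",
    "percent_identity",
    "jaccard_similarity",
    "backbone_identity",
    "combined_score",
    "similarity_matrix",
    "BGCSimilarity",
]

#: Backbone-enzyme domain types considered in the identity component:
#: NRPS core domains (AMP-binding = adenylation, Condensation, PCP /
#: PP-binding = thiolation, TE = thioesterase), PKS core domains, and
#: dimethylallyl tryptophan synthase.
DEFAULT_BACKBONE_TYPES = frozenset(
    {
        "AMP-binding",
        "Condensation",
        "PCP",
        "PP-binding",
        "PKS_KS",
        "PKS_AT",
        "DMAT",
        "TE",
    }
)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for pairwise global (Needleman–Wunsch) alignment.

    BLOSUM62 substitution scores with affine gaps: a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  End gaps are penalized like any
    other gap, so length mismatch between domains lowers identity.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -abs(self.gap_open)
        aligner.extend_gap_score = -abs(self.gap_extend)
        aligner.mode = "global"
        return aligner


@dataclass(frozen=True)
class ScoreWeights:
    """Weights of the combined similarity score; must sum to 1."""

    w_id: float = 0.8
    w_jac: float = 0.2

    def __post_init__(self) -> None:
        if self.w_id < 0 or self.w_jac < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_id + self.w_jac - 1.0) > 1e-9:
            raise ValueError(
                f"weights must sum to 1, got {self.w_id} + {self.w_jac}"
            )


@dataclass(frozen=True)
class SimilarityEdge:
    """A scored, unordered cluster pair."""

    cluster_a: str
    cluster_b: str
    seq_identity: float
    jaccard: float
    score: float
    n_matched_backbone_pairs: int


@dataclass(frozen=True)
class GappedAlignment:
    """A pairwise global alignment: two equal-length gapped strings."""

    a: str
    b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped strings differ in length")


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq.upper()) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{name}: invalid residues {sorted(bad)}")


def global_align(
    a: str, b: str, params: AlignmentParams | None = None
) -> GappedAlignment:
    """Optimal global alignment of two protein sequences.

    Deterministic: of co-optimal alignments the aligner's first traceback
    is returned, which prefers diagonal moves.
    """
    params = params or AlignmentParams()
    _check_protein(a, "a")
    _check_protein(b, "b")
    aligner = params.make_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    return GappedAlignment(a=str(aln[0]), b=str(aln[1]), score=float(aln.score))


def percent_identity(alignment: GappedAlignment) -> float:
    """Fraction of alignment columns with identical residues.

    The denominator is the full alignment length, end gaps included, so
    truncated domains score below full-length matches.
    """
    n = len(alignment.a)
    if n == 0:
        raise ValueError("zero-length alignment")
    matches = sum(
        1 for x, y in zip(alignment.a, alignment.b) if x == y and x != "-"
    )
    return matches / n


def pairwise_identity(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Convenience: identity of the optimal global alignment of ``a`` and ``b``."""
    return percent_identity(global_align(a, b, params))


def jaccard_similarity(domains_a: set[str], domains_b: set[str]) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 when both sets are empty."""
    a, b = set(domains_a), set(domains_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def greedy_match(identity: np.ndarray) -> list[tuple[int, int, float]]:
    """Greedy best-first one-to-one matching of an identity matrix.

    Repeatedly takes the highest remaining identity (ties broken by row
    then column index), removing its row and column.  Returns
    ``(row, col, identity)`` triples; unmatched copies are ignored.
    """
    identity = np.asarray(identity, dtype=float)
    cells = sorted(
        ((i, j) for i in range(identity.shape[0]) for j in range(identity.shape[1])),
        key=lambda ij: (-identity[ij], ij[0], ij[1]),
    )
    used_rows: set[int] = set()
    used_cols: set[int] = set()
    out: list[tuple[int, int, float]] = []
    for i, j in cells:
        if i in used_rows or j in used_cols:
            continue
        used_rows.add(i)
        used_cols.add(j)
        out.append((i, j, float(identity[i, j])))
    return out


def backbone_identity(
    c1: ClusterRecord,
    c2: ClusterRecord,
    params: AlignmentParams | None = None,
    backbone_types: frozenset[str] | set[str] = DEFAULT_BACKBONE_TYPES,
) -> tuple[float, int]:
    """Median identity over matched backbone-domain pairs of two clusters.

    For every backbone type present in both clusters, copies are matched
    greedily by best pairwise identity (each copy used once); the median is
    taken over all matched pairs of all shared types.  ``(0.0, 0)`` when no
    type is shared.
    """
    shared = sorted(
        (set(c1.backbone_domains) & set(c2.backbone_domains)) & set(backbone_types)
    )
    identities: list[float] = []
    for dtype in shared:
        seqs1 = c1.backbone_domains[dtype]
        seqs2 = c2.backbone_domains[dtype]
        idm = np.array(
            [[pairwise_identity(s1, s2, params) for s2 in seqs2] for s1 in seqs1]
        )
        identities.extend(v for _, _, v in greedy_match(idm))
    if not identities:
        return 0.0, 0
    return float(statistics.median(identities)), len(identities)


def combined_score(
    seq_identity: float,
    jaccard: float,
    weights: ScoreWeights | None = None,
) -> float:
    """The weighted cluster-similarity score ``w_id·identity + w_jac·jaccard``."""
    weights = weights or ScoreWeights()
    if not (0.0 <= seq_identity <= 1.0 and 0.0 <= jaccard <= 1.0):
        raise ValueError("identity and jaccard must lie in [0, 1]")
    score = weights.w_id * seq_identity + weights.w_jac * jaccard
    return min(1.0, max(0.0, score))


@dataclass
class SimilarityResult:
    """All-pairs similarity of a cluster set.

    ``score``, ``identity`` and ``jaccard`` are symmetric DataFrames
    indexed by cluster id with unit diagonal; ``edges`` lists each
    unordered pair once (lexicographic order within a pair).
    """

    ids: list[str]
    score: pd.DataFrame
    identity: pd.DataFrame
    jaccard: pd.DataFrame
    edges: list[SimilarityEdge] = field(default_factory=list)

    def distance(self) -> pd.DataFrame:
        """``1 - score`` with an exact zero diagonal."""
        d = 1.0 - self.score
        np.fill_diagonal(d.values, 0.0)
        return d


def similarity_matrix(
    clusters: list[ClusterRecord],
    weights: ScoreWeights | None = None,
    params: AlignmentParams | None = None,
    backbone_types: frozenset[str] | set[str] = DEFAULT_BACKBONE_TYPES,
) -> SimilarityResult:
    """Score every unordered pair of clusters.

    The diagonal is 1.0 by convention.  Raises on duplicate cluster ids or
    fewer than two clusters.
    """
    weights = weights or ScoreWeights()
    ids = [c.cluster_id for c in clusters]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate cluster ids: {dupes}")
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")

    n = len(clusters)
    s = np.eye(n)
    ident = np.eye(n)
    jac = np.eye(n)
    edges: list[SimilarityEdge] = []
    for i in range(n):
        for j in range(i + 1, n):
            med_id, n_pairs = backbone_identity(
                clusters[i], clusters[j], params, backbone_types
            )
            jc = jaccard_similarity(clusters[i].domain_set, clusters[j].domain_set)
            sc = combined_score(med_id, jc, weights)
            ident[i, j] = ident[j, i] = med_id
            jac[i, j] = jac[j, i] = jc
            s[i, j] = s[j, i] = sc
            a, b = sorted((ids[i], ids[j]))
            edges.append(SimilarityEdge(a, b, med_id, jc, sc, n_pairs))
    return SimilarityResult(
        ids=ids,
        score=pd.DataFrame(s, index=ids, columns=ids),
        identity=pd.DataFrame(ident, index=ids, columns=ids),
        jaccard=pd.DataFrame(jac, index=ids, columns=ids),
        edges=edges,
    )


class BGCSimilarity(TransformerMixin, BaseEstimator):
    """Pairwise-similarity transformer over lists of :class:`ClusterRecord`.

    ``fit(X)`` stores the reference clusters; ``transform(Y)`` returns the
    |Y| × |X| combined-score matrix of new clusters against the fitted ones
    (so ``fit_transform(X)`` is the square all-pairs score matrix).  Output
    can feed :class:`~gcfkit.families.GCFClusterer` with
    ``input="similarity"`` inside an sklearn Pipeline.

    Parameters
    ----------
    w_id, w_jac:
        Weights of the identity and Jaccard components (must sum to 1).
    backbone_types:
        Backbone-domain whitelist for the identity component.
    alignment_params:
        Global-alignment scoring scheme.
    """

    def __init__(
        self,
        w_id: float = 0.8,
        w_jac: float = 0.2,
        backbone_types: frozenset[str] = DEFAULT_BACKBONE_TYPES,
        alignment_params: AlignmentParams | None = None,
    ) -> None:
        self.w_id = w_id
        self.w_jac = w_jac
        self.backbone_types = backbone_types
        self.alignment_params = alignment_params

    def _weights(self) -> ScoreWeights:
        return ScoreWeights(self.w_id, self.w_jac)

    def fit(self, X: list[ClusterRecord], y=None) -> "BGCSimilarity":
        self._weights()  # validate early
        ids = [c.cluster_id for c in X]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cluster ids")
        self.clusters_ = list(X)
        self.ids_ = ids
        return self

    def _pair_score(self, a: ClusterRecord, b: ClusterRecord) -> float:
        if a.cluster_id == b.cluster_id:
            return 1.0
        med_id, _ = backbone_identity(
            a, b, self.alignment_params, self.backbone_types
        )
        jc = jaccard_similarity(a.domain_set, b.domain_set)
        return combined_score(med_id, jc, self._weights())

    def transform(self, X: list[ClusterRecord]) -> np.ndarray:
        if not hasattr(self, "clusters_"):
            raise ValueError("BGCSimilarity is not fitted")
        out = np.empty((len(X), len(self.clusters_)))
        for i, a in enumerate(X):
            for j, b in enumerate(self.clusters_):
                out[i, j] = self._pair_score(a, b)
        return out

    def fit_transform(self, X: list[ClusterRecord], y=None) -> np.ndarray:
        self.fit(X)
        result = similarity_matrix(
            X,
            weights=self._weights(),
            params=self.alignment_params,
            backbone_types=self.backbone_types,
        )
        self.result_ = result
        return result.score.to_numpy()
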