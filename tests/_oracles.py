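"""Independent oracles used to cross-check the implementation.

These deliberately share no code with gcfkit: a three-state affine-gap
dynamic program for global alignment scores, a brute-force connected
component finder for family calling, and exhaustive enumeration of
one-to-one matchings for the backbone-pairing step.
"""

from itertools import permutations

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def gotoh_score(a: str, b: str, open_=-10.0, ext=-0.5) -> float:
    """Optimal global alignment score, affine gaps, BLOSUM62.

    A gap of length L costs ``open_ + (L - 1) * ext``; end gaps are
    penalized.  Three-state Gotoh recurrence computed independently of any
    alignment library.
    """
    sub = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(
                M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_
            )
            Y[i, j] = max(
                M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_
            )
    return float(max(M[n, m], X[n, m], Y[n, m]))


def threshold_components(dist: np.ndarray, epsilon: float) -> list[int]:
    """Partition labels from connected components of the d <= epsilon graph.

    Isolated vertices get their own (fresh) label, mirroring how singleton
    clusters are treated as their own trivial partition blocks.
    """
    n = dist.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= epsilon:
                g.add_edge(i, j)
    labels = [0] * n
    for lab, comp in enumerate(nx.connected_components(g)):
        for v in comp:
            labels[v] = lab
    return labels


def best_matching_median(identity: np.ndarray) -> float:
    """Median identity of the best one-to-one matching, by full enumeration.

    Considers every maximal matching of rows to columns and returns the
    one maximizing total identity (the target the greedy matcher
    approximates); ties resolved by the maximum, which is unique on the
    fixtures used.
    """
    import statistics

    r, c = identity.shape
    k = min(r, c)
    best_total, best_median = NEG, 0.0
    rows = range(r)
    for row_sel in permutations(rows, k):
        for col_sel in permutations(range(c), k):
            vals = [identity[i, j] for i, j in zip(row_sel, col_sel)]
            total = sum(vals)
            if total > best_total:
                best_total = total
                best_median = statistics.median(vals)
    return best_median
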