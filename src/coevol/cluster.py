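"""Residue clustering: score-to-distance transforms and complete linkage.

Scores are converted to distances by the 1-score transform (after flooring
negative correlations at 0); joint entropy is already distance-like — a low
joint entropy means the pair is jointly conserved, i.e. close — and is used
directly.  Clustering is agglomerative with complete linkage (inter-cluster
distance = maximum pairwise member distance), which is monotone: merge
heights never decrease.  Ties on the merge distance are broken by the lowest
pair of cluster indices, making the tree deterministic across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .covariance import MetricMatrix
from .errors import InputError
from .msa_io import ResidueNumbering


@dataclass
class DistanceMatrix:
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    source_metric: str
    labels: ResidueNumbering

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = self.values.shape[0]
        if self.values.shape != (L, L):
            raise InputError("distance matrix must be square")
        if np.any(np.diag(self.values) != 0):
            raise InputError("distance diagonal must be zero")
        if np.any(self.values < 0):
            raise InputError("distances must be non-negative")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree.

    ``merges`` lists (cluster_a, cluster_b, height) with leaves numbered
    0..L-1 and internal clusters L, L+1, ... in merge order (the scipy
    linkage convention).
    """

    merges: list[tuple[int, int, float]]
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_linkage(self) -> np.ndarray:
        """(L-1, 4) scipy-style linkage matrix (counts in column 4)."""
        L = self.n_leaves
        sizes = {i: 1 for i in range(L)}
        Z = np.zeros((L - 1, 4))
        for k, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[L + k] = size
            Z[k] = [a, b, h, size]
        return Z


def to_distance(m: MetricMatrix) -> DistanceMatrix:
    """Convert a score matrix to a residue distance matrix.

    mi/mip/chi2: d = 1 - score (mi/mip must already be normalized; chi2 is a
    cumulative probability).  r: negatives floored at 0 first, then 1 - score.
    jentropy: the normalized entropy itself is the distance.  The diagonal is
    forced to 0 and all entries clamped to [0, 1].
    """
    v = m.values.copy()
    if m.metric in ("mi", "mip"):
        if not m.normalized:
            raise InputError(f"{m.metric} matrix must be normalized before clustering")
        d = 1.0 - v
    elif m.metric == "chi2":
        d = 1.0 - v
    elif m.metric == "r":
        d = 1.0 - np.maximum(v, 0.0)
    elif m.metric == "jentropy":
        d = v
    else:
        raise InputError(f"unknown metric {m.metric!r}")
    d = np.clip(d, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # guard symmetry against rounding
    return DistanceMatrix(values=d, source_metric=m.metric, labels=m.labels)


def complete_linkage(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative complete-linkage clustering of the residues.

    At each step the two active clusters with minimal maximum pairwise
    distance are merged; ties are broken by the lower (first) pair of cluster
    ids.  Heights are the merge distances and are non-decreasing.
    """
    L = d.size
    if L < 2:
        raise InputError("need at least 2 residues to cluster")
    # dist[c1][c2]: complete-linkage distance between active clusters
    dist: dict[int, dict[int, float]] = {
        i: {j: float(d.values[i, j]) for j in range(L) if j != i} for i in range(L)
    }
    active = set(range(L))
    merges: list[tuple[int, int, float]] = []
    next_id = L
    for _ in range(L - 1):
        best: Optional[tuple[float, int, int]] = None
        for a in sorted(active):
            for b in sorted(dist[a]):
                if b <= a:
                    continue
                cand = (dist[a][b], a, b)
                if best is None or cand < best:
                    best = cand
        h, a, b = best  # type: ignore[misc]
        merges.append((a, b, h))
        new = {
            c: max(dist[a][c], dist[b][c])
            for c in active
            if c not in (a, b)
        }
        for c in new:
            dist[c].pop(a, None)
            dist[c].pop(b, None)
            dist[c][next_id] = new[c]
        dist.pop(a)
        dist.pop(b)
        dist[next_id] = new
        active.discard(a)
        active.discard(b)
        active.add(next_id)
        next_id += 1
    return Dendrogram(merges=merges, leaves=list(d.labels.labels))


_NEWICK_META = set("():;, '\"[]")


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(t: Dendrogram) -> str:
    """Serialize an ultrametric Newick string.

    Each node sits at elevation height/2 (half the merge distance, the
    ultrametric convention); a branch length is the elevation difference to
    the parent, so a leaf's branch equals half its first merge height.
    """
    L = t.n_leaves
    elev: dict[int, float] = {i: 0.0 for i in range(L)}
    first_leaf: dict[int, int] = {i: i for i in range(L)}
    text: dict[int, str] = {i: _quote_label(lab) for i, lab in enumerate(t.leaves)}
    for k, (a, b, h) in enumerate(t.merges):
        node = L + k
        e = h / 2.0
        elev[node] = e
        # children ordered by their smallest leaf index, for a stable layout
        if first_leaf[b] < first_leaf[a]:
            a, b = b, a
        first_leaf[node] = first_leaf[a]
        bl_a = e - elev[a]
        bl_b = e - elev[b]
        text[node] = f"({text[a]}:{bl_a:.10g},{text[b]}:{bl_b:.10g})"
    root = L + len(t.merges) - 1
    return text[root] + ";"


def cut_clusters(t: Dendrogram, height: float) -> list[list[str]]:
    """Partition residues by cutting all merges strictly above ``height``.

    Merges at exactly the cut height are kept.  Clusters are returned in
    order of their smallest leaf index; singletons are allowed.
    """
    if height < 0:
        raise InputError("cut height must be non-negative")
    L = t.n_leaves
    parent = list(range(L + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h) in enumerate(t.merges):
        if h <= height:
            node = L + k
            parent[find(a)] = node
            parent[find(b)] = node
    groups: dict[int, list[int]] = {}
    for i in range(L):
        groups.setdefault(find(i), []).append(i)
    ordered = sorted(groups.values(), key=lambda g: g[0])
    return [[t.leaves[i] for i in g] for g in ordered]
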