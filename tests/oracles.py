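"""Independent brute-force reference implementations used only by tests.

These deliberately avoid numpy vectorization and any code path shared with
the package: plain Python loops, dict counting, math.log.  They evaluate the
metric definitions directly so the package can be checked against them.
"""

import math

GAP = "-"


def naive_pair_counts(rows, query, weights, i, j):
    """4-state weighted counts for columns i, j over rows non-gapped at both."""
    c = {("X", "Y"): 0.0, ("X", "!Y"): 0.0, ("!X", "Y"): 0.0, ("!X", "!Y"): 0.0}
    n_eff = 0.0
    for row, w in zip(rows, weights):
        if row[i] == GAP or row[j] == GAP:
            continue
        x = "X" if row[i] == query[i] else "!X"
        y = "Y" if row[j] == query[j] else "!Y"
        c[(x, y)] += w
        n_eff += w
    return c, n_eff


def naive_frequencies(c, n_eff, lam=1.0):
    denom = n_eff + lam
    pj = {k: v / denom for k, v in c.items()}
    pi = {
        "X": (c[("X", "Y")] + c[("X", "!Y")]) / denom,
        "!X": (c[("!X", "Y")] + c[("!X", "!Y")]) / denom,
    }
    pyy = {
        "Y": (c[("X", "Y")] + c[("!X", "Y")]) / denom,
        "!Y": (c[("X", "!Y")] + c[("!X", "!Y")]) / denom,
    }
    return pj, pi, pyy


def naive_mi(rows, query, weights, i, j):
    c, n_eff = naive_pair_counts(rows, query, weights, i, j)
    pj, pi, pyy = naive_frequencies(c, n_eff)
    mi = 0.0
    for x in ("X", "!X"):
        for y in ("Y", "!Y"):
            p = pj[(x, y)]
            e = pi[x] * pyy[y]
            if p > 0 and e > 0:
                mi += p * math.log(p / e)
    return max(mi, 0.0)


def naive_chi2(rows, query, weights, i, j):
    c, n_eff = naive_pair_counts(rows, query, weights, i, j)
    pj, pi, pyy = naive_frequencies(c, n_eff)
    x2 = 0.0
    for x in ("X", "!X"):
        for y in ("Y", "!Y"):
            e = pi[x] * pyy[y]
            if e > 0:
                x2 += (pj[(x, y)] - e) ** 2 / e
    return x2


def naive_joint_entropy(rows, query, weights, i, j):
    c, n_eff = naive_pair_counts(rows, query, weights, i, j)
    pj, _, _ = naive_frequencies(c, n_eff)
    s = 0.0
    for p in pj.values():
        if p > 0:
            s -= p * math.log(p)
    return s / math.log(4.0)


def naive_position_stats(scores_col, weights):
    """Weighted mean and population sd; scores_col holds None for gaps."""
    pairs = [(s, w) for s, w in zip(scores_col, weights) if s is not None]
    wsum = sum(w for _, w in pairs)
    if wsum <= 0:
        return 0.0, 0.0
    mean = sum(s * w for s, w in pairs) / wsum
    var = sum(w * (s - mean) ** 2 for s, w in pairs) / wsum
    return mean, math.sqrt(max(var, 0.0))


def naive_pearson(scores_i, scores_j, weights):
    """Weighted Pearson r per the covariance-sum definition.

    scores_* hold None for rows gapped at that position; per-position stats
    use that position's valid rows, the sum runs over rows valid at both.
    """
    mean_i, sd_i = naive_position_stats(scores_i, weights)
    mean_j, sd_j = naive_position_stats(scores_j, weights)
    if sd_i == 0 or sd_j == 0:
        return 0.0
    num = 0.0
    n_eff = 0.0
    for si, sj, w in zip(scores_i, scores_j, weights):
        if si is None or sj is None:
            continue
        num += w * (si - mean_i) * (sj - mean_j) / (sd_i * sd_j)
        n_eff += w
    if n_eff <= 0:
        return 0.0
    return max(-1.0, min(1.0, num / n_eff))


def naive_apc(mi_matrix):
    """Element-wise APC/MIp on a square list-of-lists raw MI matrix."""
    L = len(mi_matrix)
    row_means = [
        sum(mi_matrix[a][b] for b in range(L) if b != a) / (L - 1) for a in range(L)
    ]
    off = [mi_matrix[a][b] for a in range(L) for b in range(L) if a != b]
    grand = sum(off) / len(off)
    out = [row[:] for row in mi_matrix]
    for a in range(L):
        for b in range(L):
            if a == b:
                continue
            if grand == 0:
                out[a][b] = mi_matrix[a][b]
            else:
                out[a][b] = max(mi_matrix[a][b] - row_means[a] * row_means[b] / grand, 0.0)
    return out


def naive_complete_linkage(dist):
    """Brute-force complete-linkage agglomeration on a nested-list matrix.

    Clusters are frozensets of leaf indices; returns a list of
    (set_a, set_b, height) with ties broken by creation order of clusters.
    Independent of the package's id bookkeeping: cluster order tracked in a
    plain list.
    """
    clusters = [frozenset([i]) for i in range(len(dist))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[x][y] for x in clusters[a] for y in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((clusters[a], clusters[b], d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
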