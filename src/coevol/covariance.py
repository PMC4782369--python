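"""Pairwise covariance and conservation metrics over alignment columns.

Every frequency-based metric uses the four-state model: at each position an
aligned residue is classified only as equal (X) or unequal (!X) to the query
residue there, so a column pair has the joint states (X,Y), (X,!Y), (!X,Y),
(!X,!Y).  Rows gapped at either position are excluded from that pair; the
effective count N_eff is the sum of the remaining rows' weights, and every
frequency is a pseudocounted ratio

    p(s) = c(s) / (N_eff + lambda),      lambda = 1.

Metrics
-------
mi
    mutual information sum_x sum_y p(x,y) log[p(x,y) / (p_i(x) p_j(y))]
    in natural-log units, min-max normalized to [0, 1] off-diagonal.
mip
    MI minus the average product correction APC(a,b) =
    MI(a,.) MI(b,.) / mean(MI) computed on raw MI; negative values floored
    at 0, then min-max normalized.
chi2
    sum of (p(x,y) - p_i(x) p_j(y))^2 / (p_i(x) p_j(y)) evaluated literally
    on the pseudocounted frequencies, reported as the df = 1 chi-square
    cumulative probability.
r
    weighted Pearson correlation of per-row PSSM similarity scores at the two
    positions (population form; falls back to BLOSUM62 column scores when no
    PSSM is supplied).
jentropy
    joint Shannon entropy of the 4 states, normalized by 1/log(4); low values
    mean the pair is jointly conserved.

Matrix diagonals carry per-residue conservation: the weighted pseudocounted
frequency of the query residue for mi/mip/chi2, and the 20-state individual
entropy (from the PSSM probability rows, normalized by 1/log(20)) for
jentropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import chi2 as _chi2_dist

from .errors import InputError
from .msa_io import GAP, PSSM_ALPHABET, Alignment, PSSMProfile, ResidueNumbering
from .weighting import WeightVector, compute_weights

METRICS = ("mi", "mip", "chi2", "r", "jentropy")

#: Pseudocount lambda added to the frequency denominator.
PSEUDOCOUNT = 1.0


# ---------------------------------------------------------------------------
# scalar (per-pair) operations
# ---------------------------------------------------------------------------

@dataclass
class PairStateDistribution:
    """Weighted 4-state counts and pseudocounted frequencies for a column pair.

    State order throughout: (X,Y), (X,!Y), (!X,Y), (!X,!Y).
    """

    counts: np.ndarray  # 4 weighted counts
    n_eff: float
    lam: float = PSEUDOCOUNT
    p_joint: np.ndarray = field(init=False)
    p_i: np.ndarray = field(init=False)  # (p_i(X), p_i(!X))
    p_j: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        denom = self.n_eff + self.lam
        self.p_joint = self.counts / denom
        c = self.counts
        self.p_i = np.array([c[0] + c[1], c[2] + c[3]]) / denom
        self.p_j = np.array([c[0] + c[2], c[1] + c[3]]) / denom


def pair_distribution(
    aln: Alignment, w: WeightVector, i: int, j: int, lam: float = PSEUDOCOUNT
) -> PairStateDistribution:
    """Weighted 4-state distribution for columns i and j.

    Rows gapped at either column are excluded; marginals come from the same
    row subset as the joint counts so the independence structure is
    consistent.
    """
    L = aln.length
    if not (0 <= i < L and 0 <= j < L):
        raise InputError(f"column index out of range: ({i}, {j}) for L={L}")
    qi, qj = aln.query_seq[i], aln.query_seq[j]
    counts = np.zeros(4)
    n_eff = 0.0
    for row, wl in zip(aln.rows, w.weights):
        ci, cj = row[i], row[j]
        if ci == GAP or cj == GAP:
            continue
        state = (0 if ci == qi else 2) + (0 if cj == qj else 1)
        counts[state] += wl
        n_eff += wl
    return PairStateDistribution(counts=counts, n_eff=n_eff, lam=lam)


def mutual_information(d: PairStateDistribution) -> float:
    """Four-state mutual information in nats (floored at 0)."""
    mi = 0.0
    for x in range(2):
        for y in range(2):
            p = d.p_joint[2 * x + y]
            e = d.p_i[x] * d.p_j[y]
            if p > 0 and e > 0:
                mi += p * math.log(p / e)
    return max(mi, 0.0)


def chi_square(d: PairStateDistribution) -> float:
    """Chi-square-shaped deviation from independence on the frequencies.

    Evaluated literally on the pseudocounted frequencies (no rescaling to
    counts); terms with zero expected frequency are skipped.
    """
    x2 = 0.0
    for x in range(2):
        for y in range(2):
            p = d.p_joint[2 * x + y]
            e = d.p_i[x] * d.p_j[y]
            if e > 0:
                x2 += (p - e) ** 2 / e
    return x2


def chi2_to_cumulative(x: float) -> float:
    """Cumulative probability P(X <= x) of the chi-square law with df = 1."""
    if x < 0:
        raise InputError("chi-square statistic must be non-negative")
    return float(_chi2_dist.cdf(x, df=1))


def joint_entropy(d: PairStateDistribution) -> float:
    """Normalized joint Shannon entropy of the 4 states, in [0, 1]."""
    s = 0.0
    for p in d.p_joint:
        if p > 0:
            s -= p * math.log(p)
    return s / math.log(4.0)


@dataclass
class PositionSimilarityStats:
    """Weighted mean/sd of per-row similarity scores at one position."""

    s_values: np.ndarray  # score per contributing row
    weights: np.ndarray  # matching weights
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.s_values = np.asarray(self.s_values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        wsum = self.weights.sum()
        if wsum <= 0:
            self.mean = 0.0
            self.sd = 0.0
            return
        self.mean = float(np.average(self.s_values, weights=self.weights))
        var = float(np.average((self.s_values - self.mean) ** 2, weights=self.weights))
        self.sd = math.sqrt(max(var, 0.0))


def _similarity_scores(
    aln: Alignment, pssm: Optional[PSSMProfile]
) -> np.ndarray:
    """(n_rows, L) matrix of similarity scores s_il; NaN where undefined.

    With a PSSM, s_il is the PSSM log-odds of row l's residue at the query
    position i.  Without one, the BLOSUM62 score of (query residue, row
    residue) is used.  Gaps and residues outside the 20-letter alphabet get
    NaN and are treated as gaps at that position.
    """
    L = aln.length
    n = aln.n_rows
    s = np.full((n, L), np.nan)
    if pssm is not None:
        if pssm.length != L:
            raise InputError(
                f"PSSM length {pssm.length} does not match alignment L={L}"
            )
        lookup = {aa: k for k, aa in enumerate(PSSM_ALPHABET)}
        for l, row in enumerate(aln.rows):
            for i, c in enumerate(row):
                k = lookup.get(c)
                if k is not None:
                    s[l, i] = pssm.scores[i, k]
    else:
        from Bio.Align import substitution_matrices

        b62 = substitution_matrices.load("BLOSUM62")
        alpha = set(PSSM_ALPHABET)
        for l, row in enumerate(aln.rows):
            for i, c in enumerate(row):
                q = aln.query_seq[i]
                if c in alpha and q in alpha:
                    s[l, i] = b62[q, c]
    return s


def position_similarity_stats(
    aln: Alignment, w: WeightVector, pssm: Optional[PSSMProfile], i: int
) -> PositionSimilarityStats:
    """Weighted similarity-score statistics at position i.

    Rows gapped (or with a non-standard residue) at i are excluded.
    """
    s = _similarity_scores(aln, pssm)[:, i]
    ok = ~np.isnan(s)
    return PositionSimilarityStats(s_values=s[ok], weights=w.weights[ok])


def pearson_r(
    aln: Alignment, w: WeightVector, pssm: Optional[PSSMProfile], i: int, j: int
) -> float:
    """Weighted Pearson correlation of similarity scores at columns i and j.

    Position means and standard deviations are the per-position weighted
    population statistics; the covariance sum runs over rows valid at both
    positions with N_eff their summed weight.  Returns 0 when either position
    has zero score variance (a totally conserved column carries no signal).
    """
    s = _similarity_scores(aln, pssm)
    stats_i = PositionSimilarityStats(
        s_values=s[~np.isnan(s[:, i]), i], weights=w.weights[~np.isnan(s[:, i])]
    )
    stats_j = PositionSimilarityStats(
        s_values=s[~np.isnan(s[:, j]), j], weights=w.weights[~np.isnan(s[:, j])]
    )
    if stats_i.sd == 0 or stats_j.sd == 0:
        return 0.0
    both = ~np.isnan(s[:, i]) & ~np.isnan(s[:, j])
    n_eff = w.weights[both].sum()
    if n_eff <= 0:
        return 0.0
    num = np.sum(
        w.weights[both]
        * (s[both, i] - stats_i.mean)
        * (s[both, j] - stats_j.mean)
    ) / (stats_i.sd * stats_j.sd)
    return float(np.clip(num / n_eff, -1.0, 1.0))


def individual_entropy(pssm: PSSMProfile, i: int) -> float:
    """20-state Shannon entropy of PSSM probability row i, normalized by ln 20."""
    p = pssm.probs[i]
    mask = p > 0
    if not mask.any():
        return 0.0
    return float(-(p[mask] * np.log(p[mask])).sum() / math.log(20.0))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

@dataclass
class MetricMatrix:
    """Symmetric L x L score matrix with its provenance metadata."""

    metric: str
    weighting: str
    values: np.ndarray
    diagonal_kind: str  # residue_frequency | individual_entropy
    normalized: bool
    labels: ResidueNumbering
    similarity_source: str = "pssm"  # pssm | blosum62 | msa_frequencies | n/a

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = self.values.shape[0]
        if self.values.shape != (L, L):
            raise InputError("matrix must be square")
        if len(self.labels) != L:
            raise InputError("labels must match matrix size")

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        m = ~np.eye(self.size, dtype=bool)
        return self.values[m]


def _four_state_counts(
    aln: Alignment, w: WeightVector
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized weighted 4-state counts for every column pair.

    Returns (c_xy, c_xny, c_nxy, c_nxny, n_eff), each (L, L), where c_xy[i, j]
    sums the weights of rows matching the query at both i and j, etc.
    """
    chars = aln.char_matrix()
    q = np.array(list(aln.query_seq), dtype="U1")
    ng = chars != GAP
    match = (chars == q[None, :]) & ng
    mism = (~(chars == q[None, :])) & ng
    wm = match * w.weights[:, None]
    wn = mism * w.weights[:, None]
    c_xy = wm.T @ match
    c_xny = wm.T @ mism
    c_nxy = wn.T @ match
    c_nxny = wn.T @ mism
    n_eff = c_xy + c_xny + c_nxy + c_nxny
    return c_xy, c_xny, c_nxy, c_nxny, n_eff


def _pair_frequencies(aln: Alignment, w: WeightVector, lam: float = PSEUDOCOUNT):
    c_xy, c_xny, c_nxy, c_nxny, n_eff = _four_state_counts(aln, w)
    denom = n_eff + lam
    pj = [c / denom for c in (c_xy, c_xny, c_nxy, c_nxny)]
    pi_x = (c_xy + c_xny) / denom
    pi_nx = (c_nxy + c_nxny) / denom
    pj_y = (c_xy + c_nxy) / denom
    pj_ny = (c_xny + c_nxny) / denom
    return pj, (pi_x, pi_nx), (pj_y, pj_ny), n_eff


def _xlogy_ratio(p: np.ndarray, e: np.ndarray) -> np.ndarray:
    """p * log(p / e) with 0 * log(.) = 0 and zero-expected terms skipped."""
    out = np.zeros_like(p)
    ok = (p > 0) & (e > 0)
    out[ok] = p[ok] * np.log(p[ok] / e[ok])
    return out


def raw_metric_matrix(
    aln: Alignment,
    metric: str,
    w: WeightVector,
    pssm: Optional[PSSMProfile] = None,
) -> np.ndarray:
    """Raw (pre-normalization) L x L values for mi/chi2/r/jentropy.

    'mi' returns un-normalized nats; 'chi2' the raw statistic (not the CDF);
    'r' the clamped correlation; 'jentropy' the 1/ln4-normalized entropy.
    Diagonals are 0 here; :func:`build_matrix` fills their semantics.
    """
    L = aln.length
    if metric in ("mi", "mip"):
        pj, pi, pjm, _ = _pair_frequencies(aln, w)
        mi = (
            _xlogy_ratio(pj[0], pi[0] * pjm[0])
            + _xlogy_ratio(pj[1], pi[0] * pjm[1])
            + _xlogy_ratio(pj[2], pi[1] * pjm[0])
            + _xlogy_ratio(pj[3], pi[1] * pjm[1])
        )
        np.maximum(mi, 0.0, out=mi)  # analytic non-negativity
        np.fill_diagonal(mi, 0.0)
        return mi
    if metric == "chi2":
        pj, pi, pjm, _ = _pair_frequencies(aln, w)
        x2 = np.zeros((L, L))
        for p, e in (
            (pj[0], pi[0] * pjm[0]),
            (pj[1], pi[0] * pjm[1]),
            (pj[2], pi[1] * pjm[0]),
            (pj[3], pi[1] * pjm[1]),
        ):
            ok = e > 0
            x2[ok] += (p[ok] - e[ok]) ** 2 / e[ok]
        np.fill_diagonal(x2, 0.0)
        return x2
    if metric == "jentropy":
        pj, _, _, _ = _pair_frequencies(aln, w)
        s = np.zeros((L, L))
        for p in pj:
            ok = p > 0
            s[ok] -= p[ok] * np.log(p[ok])
        s /= math.log(4.0)
        np.fill_diagonal(s, 0.0)
        return s
    if metric == "r":
        s = _similarity_scores(aln, pssm)
        valid = ~np.isnan(s)
        wcol = valid * w.weights[:, None]
        wsum = wcol.sum(axis=0)
        safe = np.maximum(wsum, 1e-300)
        s0 = np.where(valid, s, 0.0)
        mean = (s0 * wcol).sum(axis=0) / safe
        var = ((s0 - mean[None, :]) ** 2 * wcol).sum(axis=0) / safe
        sd = np.sqrt(np.maximum(var, 0.0))
        z = np.where(valid, s0 - mean[None, :], 0.0)
        num = (z * (w.weights[:, None] * valid)).T @ z
        n_eff = (valid * w.weights[:, None]).T.astype(float) @ valid
        with np.errstate(invalid="ignore", divide="ignore"):
            r = num / n_eff / np.outer(sd, sd)
        r[~np.isfinite(r)] = 0.0
        r[(sd == 0), :] = 0.0
        r[:, (sd == 0)] = 0.0
        r[n_eff <= 0] = 0.0
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 0.0)
        return r
    raise InputError(f"unknown metric {metric!r}")


def apc_correct(mi: MetricMatrix) -> MetricMatrix:
    """Average product correction on a raw MI matrix.

    APC(a,b) = MI(a,.) MI(b,.) / mean(MI) using off-diagonal row means and
    the off-diagonal grand mean; MIp = MI - APC with negatives floored at 0.
    The diagonal is copied unchanged.  An all-zero MI matrix maps to itself.
    """
    if mi.metric != "mi":
        raise InputError("apc_correct expects a raw MI matrix")
    if mi.normalized:
        raise InputError("apc_correct expects un-normalized MI")
    v = mi.values
    L = mi.size
    if L < 2:
        raise InputError("need at least 2 columns for APC")
    off = ~np.eye(L, dtype=bool)
    row_means = (v.sum(axis=1) - np.diag(v)) / (L - 1)
    grand = v[off].mean()
    if grand == 0:
        mip = v.copy()
    else:
        apc = np.outer(row_means, row_means) / grand
        mip = v - apc
        np.maximum(mip, 0.0, out=mip)
        mip[np.eye(L, dtype=bool)] = np.diag(v)
    return MetricMatrix(
        metric="mip",
        weighting=mi.weighting,
        values=mip,
        diagonal_kind=mi.diagonal_kind,
        normalized=False,
        labels=mi.labels,
        similarity_source=mi.similarity_source,
    )


def minmax_normalize(m: MetricMatrix) -> MetricMatrix:
    """Min-max map of the off-diagonal entries onto [0, 1].

    The diagonal carries different semantics (residue conservation) and is
    left untouched.  A constant off-diagonal maps to all zeros.
    """
    v = m.values.copy()
    L = v.shape[0]
    off = ~np.eye(L, dtype=bool)
    lo, hi = v[off].min(), v[off].max()
    if hi > lo:
        v[off] = (v[off] - lo) / (hi - lo)
    else:
        v[off] = 0.0
    return MetricMatrix(
        metric=m.metric,
        weighting=m.weighting,
        values=v,
        diagonal_kind=m.diagonal_kind,
        normalized=True,
        labels=m.labels,
        similarity_source=m.similarity_source,
    )


def _diag_query_frequency(aln: Alignment, w: WeightVector, lam: float = PSEUDOCOUNT) -> np.ndarray:
    """Weighted pseudocounted frequency of the query residue per column."""
    chars = aln.char_matrix()
    q = np.array(list(aln.query_seq), dtype="U1")
    ng = chars != GAP
    match = (chars == q[None, :]) & ng
    c = (match * w.weights[:, None]).sum(axis=0)
    n_eff = (ng * w.weights[:, None]).sum(axis=0)
    return c / (n_eff + lam)


def _diag_msa_entropy(aln: Alignment, w: WeightVector) -> np.ndarray:
    """20-state entropy of weighted column frequencies, normalized by ln 20.

    Fallback diagonal for jentropy when no PSSM probability rows exist.
    """
    chars = aln.char_matrix()
    L = aln.length
    out = np.zeros(L)
    for i in range(L):
        col = chars[:, i]
        freqs = []
        for aa in PSSM_ALPHABET:
            freqs.append(w.weights[col == aa].sum())
        f = np.array(freqs)
        tot = f.sum()
        if tot <= 0:
            continue
        f = f / tot
        mask = f > 0
        out[i] = -(f[mask] * np.log(f[mask])).sum() / math.log(20.0)
    return out


def build_matrix(
    aln: Alignment,
    metric: str,
    scheme: str = "none",
    pssm: Optional[PSSMProfile] = None,
    numbering: Optional[ResidueNumbering] = None,
    weights: Optional[WeightVector] = None,
    scale_chi2_by_neff: bool = False,
) -> MetricMatrix:
    """Full metric matrix with post-processing and diagonal semantics.

    Post-processing per metric: mi is min-max normalized; mip applies the
    average product correction to raw MI, floors negatives, then min-max
    normalizes; chi2 converts each raw statistic to the df = 1 cumulative
    probability; r is stored as the raw correlation; jentropy stores the
    1/ln4-normalized joint entropy.

    ``scale_chi2_by_neff`` multiplies the raw chi-square statistic by the
    pair's effective count before the CDF (the count-based convention of
    OMES-style scores); off by default — the literal frequency form is the
    reference behaviour.
    """
    if metric not in METRICS:
        raise InputError(f"unknown metric {metric!r}")
    L = aln.length
    if L < 2:
        raise InputError("alignment must have at least 2 columns")
    if numbering is None:
        numbering = ResidueNumbering.default(L)
    if len(numbering) != L:
        raise InputError("numbering length does not match alignment")
    w = weights if weights is not None else compute_weights(aln, scheme)

    sim_source = "n/a"
    if metric == "r":
        sim_source = "pssm" if pssm is not None else "blosum62"
    if metric == "jentropy":
        sim_source = "pssm" if pssm is not None else "msa_frequencies"

    if metric in ("mi", "mip"):
        raw = raw_metric_matrix(aln, "mi", w)
        diag = _diag_query_frequency(aln, w)
        np.fill_diagonal(raw, diag)
        m = MetricMatrix(
            metric="mi", weighting=w.scheme, values=raw,
            diagonal_kind="residue_frequency", normalized=False,
            labels=numbering, similarity_source=sim_source,
        )
        if metric == "mip":
            m = apc_correct(m)
        m = minmax_normalize(m)
        return m
    if metric == "chi2":
        raw = raw_metric_matrix(aln, "chi2", w)
        if scale_chi2_by_neff:
            _, _, _, _, n_eff = _four_state_counts(aln, w)
            raw = raw * n_eff
        vals = _chi2_dist.cdf(raw, df=1)
        np.fill_diagonal(vals, _diag_query_frequency(aln, w))
        return MetricMatrix(
            metric="chi2", weighting=w.scheme, values=vals,
            diagonal_kind="residue_frequency", normalized=False,
            labels=numbering, similarity_source=sim_source,
        )
    if metric == "r":
        vals = raw_metric_matrix(aln, "r", w, pssm)
        np.fill_diagonal(vals, _diag_query_frequency(aln, w))
        return MetricMatrix(
            metric="r", weighting=w.scheme, values=vals,
            diagonal_kind="residue_frequency", normalized=False,
            labels=numbering, similarity_source=sim_source,
        )
    # jentropy
    vals = raw_metric_matrix(aln, "jentropy", w)
    if pssm is not None:
        diag = np.array([individual_entropy(pssm, i) for i in range(L)])
    else:
        diag = _diag_msa_entropy(aln, w)
    np.fill_diagonal(vals, diag)
    return MetricMatrix(
        metric="jentropy", weighting=w.scheme, values=vals,
        diagonal_kind="individual_entropy", normalized=False,
        labels=numbering, similarity_source=sim_source,
    )
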