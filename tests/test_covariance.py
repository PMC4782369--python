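"""Covariance metrics: distributions, scalar operations, matrices."""

import itertools
import math

import numpy as np
import pytest

from coevol import (
    MetricMatrix,
    PairStateDistribution,
    ResidueNumbering,
    WeightVector,
    apc_correct,
    build_matrix,
    chi2_to_cumulative,
    chi_square,
    compute_weights,
    individual_entropy,
    joint_entropy,
    minmax_normalize,
    mutual_information,
    pair_distribution,
    pearson_r,
    position_similarity_stats,
)
from coevol.covariance import raw_metric_matrix
from coevol.errors import InputError
from coevol.msa_io import PSSMProfile

from conftest import make_alignment, random_alignment
import oracles


def dist(counts, n_eff):
    return PairStateDistribution(counts=np.array(counts, float), n_eff=n_eff)


class TestPairDistribution:
    def test_balanced_concordant_counts(self):
        # query AA; 5 rows matching at both columns, 5 matching at neither
        rows = ["AA"] * 5 + ["CC"] * 5
        aln = make_alignment(["AA"] + rows[1:], query="AA")
        w = WeightVector.ones(10)
        d = pair_distribution(aln, w, 0, 1)
        assert np.allclose(d.counts, [5, 0, 0, 5])
        assert d.n_eff == 10
        assert d.p_joint[0] == pytest.approx(5 / 11)

    def test_gapped_row_excluded(self):
        rows = ["AA"] * 5 + ["CC"] * 4 + ["C-"]
        aln = make_alignment(rows, query="AA")
        d = pair_distribution(aln, WeightVector.ones(10), 0, 1)
        assert d.n_eff == 9

    def test_fractional_weights(self):
        aln = make_alignment(["AA"] * 4, query="AA")
        w = WeightVector("dissimilarity", np.full(4, 0.5))
        d = pair_distribution(aln, w, 0, 1)
        assert d.counts[0] == pytest.approx(2.0)
        assert d.n_eff == pytest.approx(2.0)
        assert d.p_joint[0] == pytest.approx(2 / 3)

    def test_marginal_consistency(self, rng):
        aln = random_alignment(rng, 10, 6)
        w = compute_weights(aln, "dissimilarity")
        d = pair_distribution(aln, w, 1, 4)
        c = d.counts
        assert d.p_i[0] == pytest.approx((c[0] + c[1]) / (d.n_eff + 1))
        assert d.p_j[0] == pytest.approx((c[0] + c[2]) / (d.n_eff + 1))
        assert d.n_eff == pytest.approx(c.sum())

    def test_out_of_range_column(self, toy_aln):
        with pytest.raises(InputError):
            pair_distribution(toy_aln, WeightVector.ones(5), 0, 9)


class TestScalarMetrics:
    def test_mi_hand_value_balanced(self):
        assert mutual_information(dist([5, 0, 0, 5], 10)) == pytest.approx(
            (10 / 11) * math.log(11 / 5), abs=1e-10)

    def test_mi_hand_value_all_concordant(self):
        assert mutual_information(dist([9, 0, 0, 0], 9)) == pytest.approx(
            0.9 * math.log(0.9 / 0.81), abs=1e-10)

    def test_mi_empty_distribution_is_zero(self):
        assert mutual_information(dist([0, 0, 0, 0], 0)) == 0.0

    def test_chi2_hand_value(self):
        assert chi_square(dist([5, 0, 0, 5], 10)) == pytest.approx(1.00826, abs=1e-4)

    def test_chi2_independent_columns_zero(self):
        # counts proportional to outer product -> p(x,y) = p_i p_j exactly
        # needs the pseudocount to cancel: use frequencies directly
        d = dist([4, 4, 4, 4], 16)
        # p = 4/17 each, p_i = p_j = 8/17, p_i*p_j = 64/289 != 4/17
        # exact independence on pseudocounted freqs only when counts = 0
        assert chi_square(dist([0, 0, 0, 0], 0)) == 0.0
        assert chi_square(d) > 0

    def test_chi2_cdf(self):
        assert chi2_to_cumulative(0.0) == 0.0
        assert chi2_to_cumulative(3.8415) == pytest.approx(0.95, abs=1e-4)
        assert chi2_to_cumulative(2.0) < chi2_to_cumulative(2.5)
        with pytest.raises(InputError):
            chi2_to_cumulative(-0.1)

    def test_joint_entropy_hand_values(self):
        assert joint_entropy(dist([9, 0, 0, 0], 9)) == pytest.approx(0.06840, abs=1e-4)
        assert joint_entropy(dist([1, 1, 1, 1], 4)) == pytest.approx(
            (-4 * 0.2 * math.log(0.2)) / math.log(4), abs=1e-10)
        assert joint_entropy(dist([0, 0, 0, 0], 0)) == 0.0


def profile_from_scores(scores):
    """PSSM with given integer score rows and uniform probabilities."""
    scores = np.asarray(scores, int)
    probs = np.full(scores.shape, 0.05)
    return PSSMProfile(scores=scores, probs=probs)


class TestSimilarityStats:
    def test_constant_scores(self):
        aln = make_alignment(["AA", "AA", "AA"], query="AA")
        scores = np.zeros((2, 20), int)
        scores[:, 0] = 6  # 'A' column
        stats = position_similarity_stats(aln, WeightVector.ones(3), profile_from_scores(scores), 0)
        assert stats.mean == 6 and stats.sd == 0

    def test_two_point_population_sd(self):
        aln = make_alignment(["AC", "CC"], query="AC")  # A and C at column 0
        scores = np.zeros((2, 20), int)
        scores[0, 0] = 2   # A
        scores[0, 4] = 4   # C
        stats = position_similarity_stats(aln, WeightVector.ones(2), profile_from_scores(scores), 0)
        assert stats.mean == pytest.approx(3)
        assert stats.sd == pytest.approx(1)

    def test_zero_weight_row_ignored(self):
        aln = make_alignment(["AC", "CC"], query="AC")
        scores = np.zeros((2, 20), int)
        scores[0, 0] = 2
        scores[0, 4] = 4
        w = WeightVector("dissimilarity", [1.0, 0.0])
        stats = position_similarity_stats(aln, w, profile_from_scores(scores), 0)
        assert stats.mean == pytest.approx(2) and stats.sd == 0

    def test_nonstandard_residue_treated_as_gap(self):
        aln = make_alignment(["AC", "XC"], query="AC")
        scores = np.zeros((2, 20), int)
        stats = position_similarity_stats(aln, WeightVector.ones(2), profile_from_scores(scores), 0)
        assert len(stats.s_values) == 1


class TestPearson:
    def _aln_and_pssm(self, col_i, col_j):
        """Rows whose residues at columns 0/1 index into crafted PSSM scores."""
        letters = "ARND"
        rows = [letters[k] + letters[k] for k in range(len(col_i))]
        aln = make_alignment(rows, query=rows[0])
        scores = np.zeros((2, 20), int)
        for k in range(len(col_i)):
            scores[0, k] = col_i[k]
            scores[1, k] = col_j[k]
        return aln, profile_from_scores(scores)

    def test_self_correlation_is_one(self):
        aln, pssm = self._aln_and_pssm([1, 2, 3, 4], [1, 2, 3, 4])
        w = WeightVector.ones(4)
        assert pearson_r(aln, w, pssm, 0, 0) == pytest.approx(1.0)

    def test_mirrored_scores_anticorrelate(self):
        aln, pssm = self._aln_and_pssm([1, 2, 3, 4], [4, 3, 2, 1])
        assert pearson_r(aln, WeightVector.ones(4), pssm, 0, 1) == pytest.approx(-1.0)

    def test_textbook_four_point_value(self):
        aln, pssm = self._aln_and_pssm([1, 2, 3, 4], [1, 3, 2, 4])
        assert pearson_r(aln, WeightVector.ones(4), pssm, 0, 1) == pytest.approx(0.8)

    def test_conserved_column_returns_zero(self):
        aln, pssm = self._aln_and_pssm([5, 5, 5, 5], [1, 2, 3, 4])
        assert pearson_r(aln, WeightVector.ones(4), pssm, 0, 1) == 0.0


class TestIndividualEntropy:
    def test_uniform_is_maximal(self):
        p = PSSMProfile(scores=np.zeros((1, 20), int), probs=np.full((1, 20), 0.05))
        assert individual_entropy(p, 0) == pytest.approx(1.0)

    def test_one_hot_is_zero(self):
        probs = np.zeros((1, 20))
        probs[0, 3] = 1.0
        p = PSSMProfile(scores=np.zeros((1, 20), int), probs=probs)
        assert individual_entropy(p, 0) == 0.0

    def test_two_state_value(self):
        probs = np.zeros((1, 20))
        probs[0, 0] = probs[0, 1] = 0.5
        p = PSSMProfile(scores=np.zeros((1, 20), int), probs=probs)
        assert individual_entropy(p, 0) == pytest.approx(math.log(2) / math.log(20), abs=1e-5)


class TestApcAndNormalize:
    def _matrix(self, values):
        L = len(values)
        return MetricMatrix(
            metric="mi", weighting="none", values=np.array(values, float),
            diagonal_kind="residue_frequency", normalized=False,
            labels=ResidueNumbering.default(L),
        )

    def test_constant_mi_gives_zero_mip(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0.9)
        mip = apc_correct(self._matrix(v))
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(mip.values[off], 0.0)
        assert np.allclose(np.diag(mip.values), 0.9)  # diagonal untouched

    def test_all_zero_mi_maps_to_itself(self):
        mip = apc_correct(self._matrix(np.zeros((3, 3))))
        assert np.all(mip.values == 0)

    def test_three_by_three_matches_hand_oracle(self):
        v = np.array([[0.0, 0.2, 0.4], [0.2, 0.0, 0.6], [0.4, 0.6, 0.0]])
        mip = apc_correct(self._matrix(v))
        expected = oracles.naive_apc(v.tolist())
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(mip.values[off], np.array(expected)[off], atol=1e-12)

    def test_mip_nonnegative_and_bounded_by_mi(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, 10, 6)
            w = compute_weights(aln, "none")
            raw = raw_metric_matrix(aln, "mi", w)
            m = self._matrix(raw)
            mip = apc_correct(m)
            off = ~np.eye(6, dtype=bool)
            assert np.all(mip.values[off] >= 0)
            row_means = (raw.sum(axis=1) - np.diag(raw)) / 5
            grand = raw[off].mean()
            if grand > 0:
                apc = np.outer(row_means, row_means) / grand
                assert np.all(mip.values[off][apc[off] >= 0] <= raw[off][apc[off] >= 0] + 1e-12)

    def test_minmax_examples(self):
        v = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.8], [0.5, 0.8, 0.0]])
        out = minmax_normalize(self._matrix(v)).values
        off_vals = sorted({out[i, j] for i in range(3) for j in range(3) if i != j})
        assert off_vals == pytest.approx([0.0, 0.5, 1.0])

    def test_minmax_constant_goes_to_zero(self):
        v = np.full((3, 3), 0.4)
        np.fill_diagonal(v, 0.0)
        out = minmax_normalize(self._matrix(v)).values
        assert np.all(out[~np.eye(3, dtype=bool)] == 0)

    def test_minmax_idempotent(self):
        v = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.8], [0.5, 0.8, 0.0]])
        once = minmax_normalize(self._matrix(v))
        twice = minmax_normalize(once)
        assert np.allclose(once.values, twice.values)


class TestBuildMatrix:
    @pytest.mark.parametrize("metric", ["mi", "mip", "chi2", "r", "jentropy"])
    def test_symmetry_all_metrics(self, small_msa_with_pssm, metric):
        aln, pssm = small_msa_with_pssm
        m = build_matrix(aln, metric, "dissimilarity", pssm=pssm)
        assert np.allclose(m.values, m.values.T, atol=1e-12)

    def test_mi_offdiagonal_minmax_range(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        m = build_matrix(aln, "mi", "none")
        off = m.offdiag()
        assert off.min() == pytest.approx(0.0) and off.max() == pytest.approx(1.0)
        assert m.normalized

    def test_chi2_matches_scalar_ops_pairwise(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        w = compute_weights(aln, "gap")
        m = build_matrix(aln, "chi2", "gap")
        for i, j in itertools.combinations(range(aln.length), 2):
            expected = chi2_to_cumulative(chi_square(pair_distribution(aln, w, i, j)))
            assert m.values[i, j] == pytest.approx(expected, abs=1e-10)

    def test_chi2_entries_in_unit_interval(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        m = build_matrix(aln, "chi2", "none")
        assert np.all((m.offdiag() >= 0) & (m.offdiag() <= 1))

    def test_diagonal_is_query_residue_frequency(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        w = compute_weights(aln, "none")
        m = build_matrix(aln, "chi2", "none")
        i = 0
        ng = [l for l in range(aln.n_rows) if aln.rows[l][i] != "-"]
        match = sum(1 for l in ng if aln.rows[l][i] == aln.query_seq[i])
        assert m.values[i, i] == pytest.approx(match / (len(ng) + 1))

    def test_jentropy_diagonal_from_pssm(self, small_msa_with_pssm):
        aln, pssm = small_msa_with_pssm
        m = build_matrix(aln, "jentropy", "none", pssm=pssm)
        assert m.diagonal_kind == "individual_entropy"
        for i in (0, 3):
            assert m.values[i, i] == pytest.approx(individual_entropy(pssm, i))

    def test_jentropy_diagonal_fallback_without_pssm(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        m = build_matrix(aln, "jentropy", "none")
        assert m.similarity_source == "msa_frequencies"
        assert np.all((np.diag(m.values) >= 0) & (np.diag(m.values) <= 1))

    def test_r_fallback_is_labeled(self, small_msa_with_pssm):
        aln, _ = small_msa_with_pssm
        m = build_matrix(aln, "r", "none")
        assert m.similarity_source == "blosum62"
        assert np.all(np.abs(m.offdiag()) <= 1)

    def test_scheme_none_equals_explicit_ones(self, small_msa_with_pssm):
        aln, pssm = small_msa_with_pssm
        ones = WeightVector.ones(aln.n_rows)
        for metric in ("mi", "mip", "chi2", "r", "jentropy"):
            a = build_matrix(aln, metric, "none", pssm=pssm)
            b = build_matrix(aln, metric, "none", pssm=pssm, weights=ones)
            assert np.array_equal(a.values, b.values)

    def test_all_gap_row_changes_nothing(self, small_msa_with_pssm):
        from coevol import Alignment
        aln, pssm = small_msa_with_pssm
        padded = Alignment(
            query_id=aln.query_id, query_seq=aln.query_seq,
            rows=aln.rows + ["-" * aln.length], row_ids=aln.row_ids + ["allgap"],
        )
        for scheme in ("none", "dissimilarity", "phylogeny"):
            for metric in ("mi", "mip", "chi2", "jentropy"):
                a = build_matrix(aln, metric, scheme)
                b = build_matrix(padded, metric, scheme)
                assert np.allclose(a.values, b.values, atol=1e-12)

    def test_duplication_invariance_under_phylogeny(self, rng):
        aln = random_alignment(rng, 8, 6, gap_rate=0.0)
        from coevol import Alignment
        k = 3
        dup = Alignment(
            query_id=aln.query_id, query_seq=aln.query_seq,
            rows=[r for r in aln.rows for _ in range(k)],
            row_ids=[f"{rid}_{c}" for rid in aln.row_ids for c in range(k)],
        )
        for metric in ("mi", "chi2", "jentropy"):
            a = build_matrix(aln, metric, "phylogeny")
            b = build_matrix(dup, metric, "phylogeny")
            assert np.allclose(a.values, b.values, atol=1e-10)

    def test_single_column_rejected(self):
        aln = make_alignment(["A", "C"])
        with pytest.raises(InputError):
            build_matrix(aln, "mi", "none")

    def test_oracle_equivalence_random_alignments(self, rng):
        """Raw MI / chi2 / S / r match brute-force evaluation per pair."""
        for _ in range(8):
            aln = random_alignment(rng)
            for scheme in ("none", "dissimilarity", "gap", "phylogeny"):
                w = compute_weights(aln, scheme)
                wl = list(w.weights)
                mi = raw_metric_matrix(aln, "mi", w)
                x2 = raw_metric_matrix(aln, "chi2", w)
                s = raw_metric_matrix(aln, "jentropy", w)
                for i, j in itertools.combinations(range(aln.length), 2):
                    assert mi[i, j] == pytest.approx(
                        oracles.naive_mi(aln.rows, aln.query_seq, wl, i, j), abs=1e-10)
                    assert x2[i, j] == pytest.approx(
                        oracles.naive_chi2(aln.rows, aln.query_seq, wl, i, j), abs=1e-10)
                    assert s[i, j] == pytest.approx(
                        oracles.naive_joint_entropy(aln.rows, aln.query_seq, wl, i, j), abs=1e-10)
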