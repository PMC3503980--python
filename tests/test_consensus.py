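"""Naive-Bayes posterior construction and posterior-matrix dynamic programming."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metathread.consensus import (
    NaiveBayesAligner,
    collect_evidence,
    confidence_bin,
    consensus_alignment,
    consensus_for_target,
    needleman_wunsch_posterior,
    posterior_matrix,
    train_alignment_nb,
)
from metathread.io_model import ThreadingHit


def hit(method, pairs, template="Q", score=1.0):
    return ThreadingHit(
        method=method,
        template_id=template,
        library="chain",
        raw_score=score,
        score_type="zscore",
        alignment=pairs,
    )


class TestEvidence:
    def test_indicator_and_confidence_collection(self):
        hits = [
            hit("a", [(1, 1), (2, 2)]),
            hit("b", [(1, 1)]),
            hit("c", [(2, 2)]),
        ]
        ev = collect_evidence(hits, 1, 1, roster=["a", "b", "c", "d"],
                              confidences={"a": 0.9, "b": 0.5, "c": 0.2})
        assert ev.indicators.tolist() == [1, 1, 0, 0]
        assert ev.confidences.tolist() == [0.9, 0.5, 0.2, 0.0]

    def test_duplicate_hits_counted_once(self):
        hits = [hit("a", [(1, 1)]), hit("a", [(1, 1)])]
        ev = collect_evidence(hits, 1, 1, roster=["a"])
        assert ev.indicators.tolist() == [1]

    def test_confidence_bins(self):
        assert confidence_bin(0.0) == 0
        assert confidence_bin(0.19) == 0
        assert confidence_bin(0.2) == 1
        assert confidence_bin(1.0) == 4


def _hand_bayes_tables(ind, bins, y, n_bins=5):
    """Independent re-derivation of the smoothed NB tables."""
    n_methods = ind.shape[1]
    prior = {c: (y == c).sum() / len(y) for c in (0, 1)}
    p_ind = {}
    p_bin = {}
    for c in (0, 1):
        for k in range(n_methods):
            sub = ind[y == c, k]
            for v in (0, 1):
                p_ind[(k, c, v)] = ((sub == v).sum() + 1) / (len(sub) + 2)
            subb = bins[y == c, k]
            for b in range(n_bins):
                p_bin[(k, c, b)] = ((subb == b).sum() + 1) / (len(subb) + n_bins)
    return prior, p_ind, p_bin


def _hand_posterior(prior, p_ind, p_bin, ind_row, bin_row):
    num = prior[1]
    den = prior[0]
    for k, (v, b) in enumerate(zip(ind_row, bin_row)):
        num *= p_ind[(k, 1, v)] * p_bin[(k, 1, b)]
        den *= p_ind[(k, 0, v)] * p_bin[(k, 0, b)]
    return num / (num + den)


class TestNaiveBayes:
    def fixture_data(self):
        # hand-built 2-method, 8-sample training set
        ind = np.array(
            [[1, 1], [1, 0], [0, 1], [1, 1], [0, 0], [0, 0], [1, 0], [0, 0]]
        )
        bins = np.array(
            [[4, 3], [4, 3], [2, 1], [4, 4], [0, 0], [1, 0], [2, 2], [0, 1]]
        )
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return ind, bins, y

    def test_posteriors_equal_hand_applied_bayes_rule(self):
        ind, bins, y = self.fixture_data()
        nb = train_alignment_nb(ind, bins, y, roster=["a", "b"])
        prior, p_ind, p_bin = _hand_bayes_tables(ind, bins, y)
        for ind_row, bin_row in itertools.product(
            itertools.product((0, 1), repeat=2),
            itertools.product(range(5), repeat=2),
        ):
            expected = _hand_posterior(prior, p_ind, p_bin, ind_row, bin_row)
            got = nb.posterior(
                np.array([ind_row]), np.array([bin_row])
            )[0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_uninformative_features_collapse_to_prior(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = np.arange(n) % 2
        ind = rng.integers(0, 2, size=(n, 2))
        bins = rng.integers(0, 5, size=(n, 2))
        nb = train_alignment_nb(ind, bins, y, roster=["a", "b"])
        post = nb.posterior(np.array([[0, 1]]), np.array([[2, 3]]))[0]
        assert post == pytest.approx(0.5, abs=0.1)

    def test_smoothing_prevents_degenerate_posteriors(self):
        # method "b" indicator is constant 0 in training; an unseen 1 must
        # still yield a finite, non-extreme posterior
        ind = np.array([[1, 0], [1, 0], [0, 0], [0, 0]])
        bins = np.zeros((4, 2), dtype=int)
        y = np.array([1, 1, 0, 0])
        nb = train_alignment_nb(ind, bins, y, roster=["a", "b"])
        post = nb.posterior(np.array([[1, 1]]), np.array([[0, 0]]))[0]
        assert 0.0 < post < 1.0


class TestPosteriorMatrix:
    def make_nb(self):
        ind, bins, y = TestNaiveBayes().fixture_data()
        return train_alignment_nb(ind, bins, y, roster=["a", "b"])

    def test_4x4_matrix_equals_hand_bayes(self):
        nb = self.make_nb()
        hits = [hit("a", [(1, 1), (2, 2), (3, 3)]), hit("b", [(1, 1), (4, 4)])]
        confs = {"a": 0.9, "b": 0.3}
        pm = posterior_matrix(nb, hits, 4, 4, confidences=confs)
        ind, bins, y = TestNaiveBayes().fixture_data()
        prior, p_ind, p_bin = _hand_bayes_tables(ind, bins, y)
        bin_row = (confidence_bin(0.9), confidence_bin(0.3))
        a_pairs = {(1, 1), (2, 2), (3, 3)}
        b_pairs = {(1, 1), (4, 4)}
        for i in range(1, 5):
            for j in range(1, 5):
                ind_row = (int((i, j) in a_pairs), int((i, j) in b_pairs))
                expected = _hand_posterior(prior, p_ind, p_bin, ind_row, bin_row)
                assert pm.matrix[i - 1, j - 1] == pytest.approx(expected, abs=1e-12)

    def test_agreement_monotonicity(self):
        nb = self.make_nb()
        one = posterior_matrix(nb, [hit("a", [(1, 1)])], 2, 2,
                               confidences={"a": 0.9})
        both = posterior_matrix(
            nb, [hit("a", [(1, 1)]), hit("b", [(1, 1)])], 2, 2,
            confidences={"a": 0.9, "b": 0.9},
        )
        assert both.matrix[0, 0] > one.matrix[0, 0]

    def test_zero_evidence_cells_at_background(self):
        nb = self.make_nb()
        pm = posterior_matrix(nb, [hit("a", [(1, 1)])], 3, 3,
                              confidences={"a": 0.9})
        bins = np.array([confidence_bin(0.9), 0])
        background = nb.background_posterior(bins)
        assert pm.matrix[2, 2] == pytest.approx(background, abs=1e-12)
        assert pm.matrix[1, 0] == pytest.approx(background, abs=1e-12)

    def test_out_of_range_pair_rejected(self):
        nb = self.make_nb()
        with pytest.raises(ValueError):
            posterior_matrix(nb, [hit("a", [(1, 5)])], 4, 4)


def _enumerate_alignments_score(m, gap):
    """Brute-force optimum over all monotone matchings; internal gaps cost
    ``gap`` per gapped cell, end gaps are free."""
    nt, nq = m.shape
    best = 0.0
    for k in range(0, min(nt, nq) + 1):
        for rows in itertools.combinations(range(nt), k):
            for cols in itertools.combinations(range(nq), k):
                score = sum(m[i, j] for i, j in zip(rows, cols))
                for (i1, j1), (i2, j2) in zip(
                    zip(rows, cols), list(zip(rows, cols))[1:]
                ):
                    score -= gap * ((i2 - i1 - 1) + (j2 - j1 - 1))
                best = max(best, score)
    return best


class TestNeedlemanWunsch:
    def test_identity_matrix_diagonal(self):
        m = np.eye(5)
        pairs, score = needleman_wunsch_posterior(m, gap_penalty=0.0)
        assert pairs == [(k, k) for k in range(1, 6)]
        assert score == pytest.approx(5.0)

    def test_single_high_cell(self):
        m = np.zeros((2, 2))
        m[0, 1] = 0.9
        pairs, score = needleman_wunsch_posterior(m, gap_penalty=0.0)
        assert (1, 2) in pairs
        assert score == pytest.approx(0.9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch_posterior(np.zeros((0, 3)))

    def test_no_crossing_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = rng.uniform(size=(7, 6))
            pairs, _ = needleman_wunsch_posterior(m, gap_penalty=0.1)
            for (t1, q1), (t2, q2) in zip(pairs, pairs[1:]):
                assert t2 > t1 and q2 > q1

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_score_matches_enumeration(self, data):
        nt = data.draw(st.integers(1, 5))
        nq = data.draw(st.integers(1, 4))
        vals = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32),
                min_size=nt * nq,
                max_size=nt * nq,
            )
        )
        gap = data.draw(st.sampled_from([0.0, 0.1, 0.3]))
        m = np.array(vals, dtype=float).reshape(nt, nq)
        _, score = needleman_wunsch_posterior(m, gap_penalty=gap)
        assert score == pytest.approx(_enumerate_alignments_score(m, gap), abs=1e-9)


class TestConsensus:
    def make_nb(self):
        ind, bins, y = TestNaiveBayes().fixture_data()
        return train_alignment_nb(ind, bins, y, roster=["a", "b"])

    def test_single_method_degenerate_consensus(self):
        """With one agreeing method the consensus follows its alignment
        where the posterior beats the gap cost."""
        nb = self.make_nb()
        pairs = [(1, 1), (2, 2), (3, 3), (4, 4)]
        aln = consensus_alignment(
            nb, [hit("a", pairs)], "t", "q", 4, 4, confidences={"a": 0.9}
        )
        assert aln.pairs == pairs
        assert all(0 <= c <= 1 for c in aln.per_pair_confidence)

    def test_empty_selection_empty_output(self):
        nb = self.make_nb()
        out = consensus_for_target(
            nb, [hit("a", [(1, 1)])], "t", 4, {"Q": 4}, selected_templates=[]
        )
        assert out == {}

    def test_template_without_hits_skipped(self):
        nb = self.make_nb()
        out = consensus_for_target(
            nb,
            [hit("a", [(1, 1), (2, 2)], template="Q1")],
            "t",
            4,
            {"Q1": 4, "Q2": 4},
            selected_templates=["Q1", "Q2"],
        )
        assert set(out) == {"Q1"}
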