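"""Pair potential, contact features, thresholding and tolerant matching."""

import numpy as np
import pytest

from metathread.contacts import (
    CONTACT_NEGATIVE_RATIO,
    ContactFeatures,
    contact_feature_table,
    contact_features,
    derive_pair_potential,
    select_threshold_by_mcc,
    tolerant_match,
    train_contact_svc,
)
from metathread.io_model import ContactRecord, PairAlignment, Residue, StructureCoords
from metathread.metrics import extract_contacts


def _pair_structure(aa_pairs, spacing=12.0):
    """A chain whose only contacts are the requested residue pairs; the
    residue types at those positions are controlled."""
    n = max(max(i, j) for i, j in aa_pairs) + 2
    residues = []
    for k in range(1, n + 1):
        x = k * spacing
        residues.append(
            Residue(index=k, aa="A", atoms=[("CA", x, 0.0, 0.0)])
        )
    for i, j in aa_pairs:
        # bring a CB of i and j within 4.0 A of each other, far from the rest
        y = 50.0 + 20.0 * i
        residues[i - 1].atoms.append(("CB", 0.0, y, 0.0))
        residues[j - 1].atoms.append(("CB", 4.0, y, 0.0))
    return StructureCoords(id="p", residues=residues)


class TestPairPotential:
    def test_symmetry(self, toy_structure):
        s, _ = toy_structure
        table = derive_pair_potential([s])
        assert np.allclose(table.table, table.table.T)

    def test_empty_library_rejected(self):
        lone = StructureCoords(
            id="x", residues=[Residue(index=1, aa="A", atoms=[("CA", 0, 0, 0)])]
        )
        with pytest.raises(ValueError):
            derive_pair_potential([lone])

    def test_counts_match_hand_tally(self):
        """Single structure with known contacts: the table reproduces the
        stated log-odds formula from a by-hand contact count."""
        s = _pair_structure([(1, 7), (2, 8)])
        # residue types: make pair (1,7) = (C, W), (2,8) = (C, W) as well
        s.residues[0].aa = "C"
        s.residues[6].aa = "W"
        s.residues[1].aa = "C"
        s.residues[7].aa = "W"
        table = derive_pair_potential([s])
        contacts = extract_contacts(s)
        assert {(c.i, c.j) for c in contacts} == {(1, 7), (2, 8)}
        n = 2  # contacts, all C-W
        # endpoint frequencies: C and W each appear twice among 2n endpoints
        f = {"C": 0.5, "W": 0.5}
        exp_cw = 2 * n * f["C"] * f["W"]
        aa = "ACDEFGHIKLMNPQRSTVWY"
        ci, wi = aa.index("C"), aa.index("W")
        assert table.table[ci, wi] == pytest.approx(
            -np.log((2 + 1) / (exp_cw + 1)), abs=1e-12
        )
        # unobserved same-type pair: obs 0, exp n*f^2
        assert table.table[ci, ci] == pytest.approx(
            -np.log(1 / (n * 0.25 + 1)), abs=1e-12
        )

    def test_balanced_observation_near_zero(self):
        """When observed counts equal expectation the log-odds vanish up to
        the +1 pseudocounts."""
        s = _pair_structure([(1, 7)])
        s.residues[0].aa = "C"
        s.residues[6].aa = "W"
        table = derive_pair_potential([s])
        aa = "ACDEFGHIKLMNPQRSTVWY"
        # single C-W contact: obs(C,W)=1, exp = 2*1*0.5*0.5 = 0.5
        assert abs(table.table[aa.index("C"), aa.index("W")]) < np.log(2)


def _toy_alignment(tid, pairs, lt, lq, conf=0.8):
    return PairAlignment(
        target_id="t",
        template_id=tid,
        pairs=pairs,
        per_pair_confidence=[conf] * len(pairs),
        target_length=lt,
        template_length=lq,
    )


class TestContactFeatures:
    def setup_case(self):
        target_seq = "ACDEFGHIKLMN"  # 12 residues
        identity = [(k, k) for k in range(1, 13)]
        alignments = {
            f"T{k}": _toy_alignment(f"T{k}", identity, 12, 12, conf=0.5 + 0.1 * k)
            for k in range(1, 6)
        }
        template_contacts = {
            "T1": {ContactRecord(2, 9)},
            "T2": {ContactRecord(2, 9)},
            "T3": {ContactRecord(2, 9)},
            "T4": set(),
            "T5": {ContactRecord(3, 10)},
        }
        probabilities = {f"T{k}": 0.2 * k for k in range(1, 6)}
        potential = derive_pair_potential([_pair_structure([(1, 7)])])
        return target_seq, alignments, template_contacts, probabilities, potential

    def test_three_of_five_vote(self):
        seq, alns, tcon, probs, pot = self.setup_case()
        f = contact_features(2, 9, seq, alns, tcon, probs, pot)
        assert f.frac_templates_contact == pytest.approx(0.6)
        # voting templates T1,T2,T3 -> mean prob (0.2+0.4+0.6)/3
        assert f.mean_template_confidence == pytest.approx(0.4)
        # alignment confidence: mean over voters of mean pair confidence
        assert f.mean_alignment_confidence == pytest.approx(
            np.mean([0.6, 0.7, 0.8])
        )

    def test_uncovered_pair_sentinel(self):
        seq, alns, tcon, probs, pot = self.setup_case()
        f = contact_features(1, 12, seq, alns, tcon, probs, pot)
        assert f.frac_templates_contact == 0.0
        assert f.mean_template_confidence == 0.0
        assert f.mean_alignment_confidence == 0.0
        assert f.pair_potential == pot.lookup("A", "N")

    def test_out_of_target_rejected(self):
        seq, alns, tcon, probs, pot = self.setup_case()
        with pytest.raises(ValueError):
            contact_features(0, 9, seq, alns, tcon, probs, pot)

    def test_batch_table_matches_single_pair_route(self):
        seq, alns, tcon, probs, pot = self.setup_case()
        pairs, feats = contact_feature_table(seq, alns, tcon, probs, pot)
        for (i, j), row in zip(pairs, feats):
            single = contact_features(int(i), int(j), seq, alns, tcon, probs, pot)
            assert np.allclose(row, single.as_row(), atol=1e-12)


class TestThreshold:
    def test_clean_separation_lowest_candidate(self):
        probs = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t, mcc = select_threshold_by_mcc(probs, labels)
        assert t == 0.8  # lowest threshold achieving the maximal MCC
        assert mcc == pytest.approx(1.0)

    def test_matches_exhaustive_sweep(self):
        rng = np.random.default_rng(10)
        probs = rng.uniform(size=20)
        labels = rng.uniform(size=20) < probs  # informative labels
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        t, mcc = select_threshold_by_mcc(probs, labels)
        from metathread.metrics import mcc_from_counts

        best = max(
            (
                mcc_from_counts(
                    int(((probs >= c) & labels).sum()),
                    int(((probs >= c) & ~labels).sum()),
                    int(((probs < c) & ~labels).sum()),
                    int(((probs < c) & labels).sum()),
                ),
                -c,
            )
            for c in probs
        )
        assert mcc == pytest.approx(best[0], abs=1e-12)
        assert t == pytest.approx(-best[1])

    def test_label_permutation_mcc_near_zero(self):
        rng = np.random.default_rng(11)
        probs = rng.uniform(size=2000)
        labels = rng.permutation(probs > 0.7)
        _, mcc = select_threshold_by_mcc(probs, labels)
        assert abs(mcc) < 0.1


class TestContactSvc:
    def test_separable_features(self):
        rng = np.random.default_rng(12)
        y = rng.uniform(size=600) < 1 / (1 + CONTACT_NEGATIVE_RATIO)
        x = rng.normal(size=(600, 4)) + np.where(y[:, None], 2.0, -2.0)
        model = train_contact_svc(x, y, seed=0)
        probs = model.predict_proba(x)
        assert np.all((probs >= 0) & (probs <= 1))
        from metathread.metrics import roc_curve

        _, _, auc = roc_curve(probs, y)
        assert auc > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_contact_svc(np.zeros((10, 4)), [False] * 10)

    def test_threshold_monotonicity(self):
        """Raising the decision threshold never increases TPR or FPR."""
        rng = np.random.default_rng(13)
        probs = rng.uniform(size=500)
        labels = rng.uniform(size=500) < probs
        prev_tpr, prev_fpr = 1.1, 1.1
        for t in np.linspace(0, 1, 21):
            pred = probs >= t
            tpr = (pred & labels).sum() / max(labels.sum(), 1)
            fpr = (pred & ~labels).sum() / max((~labels).sum(), 1)
            assert tpr <= prev_tpr + 1e-12
            assert fpr <= prev_fpr + 1e-12
            prev_tpr, prev_fpr = tpr, fpr


class TestTolerantMatch:
    def c(self, i, j):
        return ContactRecord(i=i, j=j)

    def test_delta_zero_exact_intersection(self):
        pred = [self.c(1, 9), self.c(2, 10)]
        nat = [self.c(1, 9), self.c(3, 11)]
        counts = tolerant_match(pred, nat, target_length=20, delta=0)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_delta_one_shifted_pair_is_true_positive(self):
        counts = tolerant_match(
            [self.c(10, 20)], [self.c(11, 21)], target_length=30, delta=1
        )
        assert counts.tp == 1 and counts.fp == 0 and counts.fn == 0

    def test_each_native_consumable_once(self):
        pred = [self.c(10, 20), self.c(10, 21)]
        nat = [self.c(10, 20)]
        counts = tolerant_match(pred, nat, target_length=30, delta=1)
        assert counts.tp == 1 and counts.fp == 1

    def test_greedy_within_bounds_of_optimal_matching(self):
        import networkx as nx

        rng = np.random.default_rng(14)
        for trial in range(20):
            pred = {
                (int(i), int(i + 5 + g))
                for i, g in zip(
                    rng.integers(1, 25, size=6), rng.integers(0, 10, size=6)
                )
            }
            nat = {
                (int(i), int(i + 5 + g))
                for i, g in zip(
                    rng.integers(1, 25, size=6), rng.integers(0, 10, size=6)
                )
            }
            delta = int(rng.integers(0, 4))
            counts = tolerant_match(
                [self.c(*p) for p in pred],
                [self.c(*q) for q in nat],
                target_length=45,
                delta=delta,
            )
            g = nx.Graph()
            for p in pred:
                for q in nat:
                    if max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= delta:
                        g.add_edge(("p", p), ("n", q))
            optimal = len(nx.max_weight_matching(g, maxcardinality=True))
            # greedy nearest-first is a 1/2-approximation of the optimum
            assert optimal / 2 <= counts.tp <= optimal
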