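"""Long-range inter-residue contact prediction.

Contacts (heavy atoms within 4.5 A, at least four intervening residues) are
predicted from consensus target-to-template alignments and the selected
template structures.  Each candidate residue pair is described by four
features: the fraction of templates whose equivalent residues are in
contact, the mean selection confidence of those voting templates, the mean
alignment confidence at the two mapped positions, and a knowledge-based
statistical pair potential.  A Gaussian-kernel SVC with probability
calibration turns the features into contact probabilities; the reporting
threshold is chosen to maximise MCC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from metathread.io_model import (
    CONTACT_MIN_SEPARATION,
    ContactRecord,
    PairAlignment,
    StructureCoords,
)
from metathread.metrics import ConfusionCounts, extract_contacts, mcc_from_counts

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Default shipped contact-probability reporting threshold (maximises MCC on
#: the reference benchmark).
DEFAULT_CONTACT_THRESHOLD = 0.35

#: Negative:positive subsampling ratio for SVC training.
CONTACT_NEGATIVE_RATIO = 5

FEATURE_NAMES = (
    "frac_templates_contact",
    "mean_template_confidence",
    "mean_alignment_confidence",
    "pair_potential",
)


@dataclass
class PairPotentialTable:
    """Symmetric 20x20 contact log-odds potential.

    ``table[a, b] = -ln((N_obs(a,b) + 1) / (N_exp(a,b) + 1))`` where the
    expected counts come from the residue-type marginals of the observed
    contact endpoints under contact-count conservation.
    """

    table: np.ndarray
    n_contacts: int

    def __post_init__(self) -> None:
        if self.table.shape != (20, 20):
            raise ValueError("pair potential table must be 20x20")
        if not np.allclose(self.table, self.table.T):
            raise ValueError("pair potential table must be symmetric")
        if not np.all(np.isfinite(self.table)):
            raise ValueError("pair potential table must be finite")

    def lookup(self, aa_i: str, aa_j: str) -> float:
        a = _AA_INDEX.get(aa_i)
        b = _AA_INDEX.get(aa_j)
        if a is None or b is None:  # X or unknown residue type
            return 0.0
        return float(self.table[a, b])


def derive_pair_potential(structures: Iterable[StructureCoords]) -> PairPotentialTable:
    """Knowledge-based pair potential from observed contacts in a structure
    library.

    Raises when the library contributes no contacts at all.
    """
    obs = np.zeros((20, 20))
    n_total = 0
    for structure in structures:
        seq = structure.sequence
        pos = {r.index: k for k, r in enumerate(structure.residues)}
        for contact in extract_contacts(structure):
            a = _AA_INDEX.get(seq[pos[contact.i]])
            b = _AA_INDEX.get(seq[pos[contact.j]])
            if a is None or b is None:
                continue
            obs[a, b] += 1
            if a != b:
                obs[b, a] += 1
            n_total += 1
    if n_total == 0:
        raise ValueError("structure library contains no contacts")
    # endpoint marginals; each contact contributes two endpoints
    endpoints = obs.sum(axis=1)  # diagonal already counted twice via symmetry? no:
    # obs[a,a] holds the count once; its endpoints count double
    endpoints = endpoints + np.diag(obs)
    freqs = endpoints / endpoints.sum()
    expected = np.outer(freqs, freqs) * n_total * 2.0
    expected[np.diag_indices(20)] /= 2.0
    table = -np.log((obs + 1.0) / (expected + 1.0))
    table = (table + table.T) / 2.0
    return PairPotentialTable(table=table, n_contacts=n_total)


@dataclass
class ContactFeatures:
    frac_templates_contact: float
    mean_template_confidence: float
    mean_alignment_confidence: float
    pair_potential: float

    def as_row(self) -> list[float]:
        return [
            self.frac_templates_contact,
            self.mean_template_confidence,
            self.mean_alignment_confidence,
            self.pair_potential,
        ]


def contact_features(
    i: int,
    j: int,
    target_sequence: str,
    alignments: Mapping[str, PairAlignment],
    template_contacts: Mapping[str, set[ContactRecord]],
    template_probabilities: Mapping[str, float],
    potential: PairPotentialTable,
) -> ContactFeatures:
    """Features of one candidate pair (single-pair reference implementation;
    :func:`contact_feature_table` is the vectorized batch form).

    A template votes when both i and j map to template residues that are in
    contact; fractions and means run over voting templates, with an all-zero
    sentinel when no template votes.
    """
    if not 1 <= i <= len(target_sequence) or not 1 <= j <= len(target_sequence):
        raise ValueError(f"pair ({i},{j}) outside target of length {len(target_sequence)}")
    if abs(i - j) < CONTACT_MIN_SEPARATION:
        raise ValueError(f"pair ({i},{j}) violates minimum separation")
    votes = 0
    conf_sum = 0.0
    aln_conf_sum = 0.0
    n_templates = len(alignments)
    for tid, aln in alignments.items():
        mapping = aln.mapping()
        confs = {t: c for (t, _), c in zip(aln.pairs, aln.per_pair_confidence)}
        qi, qj = mapping.get(i), mapping.get(j)
        if qi is None or qj is None:
            continue
        lo, hi = min(qi, qj), max(qi, qj)
        if hi - lo < CONTACT_MIN_SEPARATION:
            continue
        if ContactRecord(i=lo, j=hi) in template_contacts.get(tid, set()):
            votes += 1
            conf_sum += template_probabilities.get(tid, 0.0)
            aln_conf_sum += 0.5 * (confs[i] + confs[j])
    if votes and n_templates:
        return ContactFeatures(
            frac_templates_contact=votes / n_templates,
            mean_template_confidence=conf_sum / votes,
            mean_alignment_confidence=aln_conf_sum / votes,
            pair_potential=potential.lookup(target_sequence[i - 1], target_sequence[j - 1]),
        )
    return ContactFeatures(
        frac_templates_contact=0.0,
        mean_template_confidence=0.0,
        mean_alignment_confidence=0.0,
        pair_potential=potential.lookup(target_sequence[i - 1], target_sequence[j - 1]),
    )


def contact_feature_table(
    target_sequence: str,
    alignments: Mapping[str, PairAlignment],
    template_contacts: Mapping[str, set[ContactRecord]],
    template_probabilities: Mapping[str, float],
    potential: PairPotentialTable,
):
    """Feature matrix over all candidate pairs of one target.

    Returns ``(pairs, features)`` where ``pairs`` is an (n, 2) array of
    1-based (i, j) with j - i >= 5 and ``features`` an (n, 4) array in the
    order of :data:`FEATURE_NAMES`.
    """
    n = len(target_sequence)
    ii, jj = np.triu_indices(n, k=CONTACT_MIN_SEPARATION)
    pairs = np.column_stack([ii + 1, jj + 1])
    votes = np.zeros(len(pairs))
    conf_sum = np.zeros(len(pairs))
    aln_conf_sum = np.zeros(len(pairs))
    n_templates = len(alignments)
    for tid, aln in alignments.items():
        # target position -> template position / per-pair confidence
        tmap = np.zeros(n + 1, dtype=int)  # 0 = unmapped
        tconf = np.zeros(n + 1)
        for (t, q), c in zip(aln.pairs, aln.per_pair_confidence):
            tmap[t] = q
            tconf[t] = c
        contacts = template_contacts.get(tid, set())
        if not contacts:
            continue
        max_q = max(c.j for c in contacts)
        size = max(max_q, int(tmap.max())) + 1
        cmat = np.zeros((size, size), dtype=bool)
        for c in contacts:
            cmat[c.i, c.j] = cmat[c.j, c.i] = True
        qi = tmap[pairs[:, 0]]
        qj = tmap[pairs[:, 1]]
        ok = (qi > 0) & (qj > 0) & (np.abs(qi - qj) >= CONTACT_MIN_SEPARATION)
        hit = np.zeros(len(pairs), dtype=bool)
        hit[ok] = cmat[qi[ok], qj[ok]]
        votes += hit
        prob = template_probabilities.get(tid, 0.0)
        conf_sum[hit] += prob
        aln_conf_sum[hit] += 0.5 * (tconf[pairs[hit, 0]] + tconf[pairs[hit, 1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = votes / n_templates if n_templates else np.zeros(len(pairs))
        mean_conf = np.where(votes > 0, conf_sum / np.maximum(votes, 1), 0.0)
        mean_aln = np.where(votes > 0, aln_conf_sum / np.maximum(votes, 1), 0.0)
    aa_idx = np.array([_AA_INDEX.get(a, -1) for a in target_sequence])
    pot = np.zeros(len(pairs))
    ai = aa_idx[pairs[:, 0] - 1]
    aj = aa_idx[pairs[:, 1] - 1]
    known = (ai >= 0) & (aj >= 0)
    pot[known] = potential.table[ai[known], aj[known]]
    features = np.column_stack([frac, mean_conf, mean_aln, pot])
    return pairs, features


# ---------------------------------------------------------------------------
# classifier and thresholding
# ---------------------------------------------------------------------------


@dataclass
class ContactModel:
    classifier: object  # calibrated Gaussian-kernel SVC
    cv_probabilities: np.ndarray | None = None

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(features)[:, 1]


def train_contact_svc(
    features: np.ndarray,
    labels: Sequence[bool],
    seed: int = 0,
    c: float = 10.0,
    gamma: str | float = "scale",
    max_train: int = 4000,
    negative_ratio: int = CONTACT_NEGATIVE_RATIO,
) -> ContactModel:
    """Gaussian-kernel contact classifier with probability calibration.

    Contact classes are extremely unbalanced, so negatives are subsampled at
    ``negative_ratio``:1 and the training set is capped at ``max_train``
    rows (stratified) before fitting.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("contact training requires both classes")
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_neg = min(len(neg), negative_ratio * len(pos))
    neg = rng.choice(neg, size=n_neg, replace=False)
    idx = np.concatenate([pos, neg])
    if len(idx) > max_train:
        keep_pos = pos[: max(2, int(max_train / (1 + negative_ratio)))]
        keep_neg = rng.choice(neg, size=max_train - len(keep_pos), replace=False)
        idx = np.concatenate([keep_pos, keep_neg])
    idx.sort()
    from sklearn.calibration import CalibratedClassifierCV
    from sklearn.model_selection import StratifiedKFold

    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", C=c, gamma=gamma),
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        ensemble=False,
    )
    clf.fit(x[idx], y[idx])
    return ContactModel(classifier=clf)


def select_threshold_by_mcc(
    probabilities: Sequence[float], labels: Sequence[bool]
) -> tuple[float, float]:
    """Probability threshold maximising MCC (ties -> lowest threshold).

    Returns ``(threshold, mcc_at_threshold)``.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("threshold selection requires both classes")
    best_t, best_mcc = 0.0, -np.inf
    for t in np.unique(p):
        pred = p >= t
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        mcc = mcc_from_counts(tp, fp, tn, fn)
        if mcc > best_mcc:
            best_t, best_mcc = float(t), mcc
    return best_t, float(best_mcc)


def predict_contacts(
    model: ContactModel,
    pairs: np.ndarray,
    features: np.ndarray,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
) -> list[ContactRecord]:
    """Contact records for pairs whose probability reaches the threshold."""
    probs = model.predict_proba(features)
    out = []
    for (i, j), p in zip(pairs, probs):
        if p >= threshold:
            out.append(ContactRecord(i=int(i), j=int(j), probability=float(p)))
    return out


# ---------------------------------------------------------------------------
# tolerant evaluation
# ---------------------------------------------------------------------------


def tolerant_match(
    predicted: Iterable[ContactRecord],
    native: Iterable[ContactRecord],
    target_length: int,
    delta: int = 0,
) -> ConfusionCounts:
    """Confusion counts under a +-delta residue tolerance.

    A prediction (i, j) may match a native contact (i', j') when
    |i - i'| <= delta and |j - j'| <= delta; matching is greedy
    nearest-first (Chebyshev distance, then native order) with every native
    contact consumable once.  With delta = 0 this is exact set intersection.
    The negative universe is every pair with j - i >= 5.
    """
    if delta not in (0, 1, 2, 3):
        raise ValueError("delta must be one of 0, 1, 2, 3")
    pred = sorted(set(predicted), key=lambda c: (c.i, c.j))
    nat = sorted(set(native), key=lambda c: (c.i, c.j))
    candidates = []
    for pi, p in enumerate(pred):
        for ni, q in enumerate(nat):
            d = max(abs(p.i - q.i), abs(p.j - q.j))
            if d <= delta:
                candidates.append((d, pi, ni))
    candidates.sort()
    used_pred: set[int] = set()
    used_nat: set[int] = set()
    tp = 0
    for _, pi, ni in candidates:
        if pi in used_pred or ni in used_nat:
            continue
        used_pred.add(pi)
        used_nat.add(ni)
        tp += 1
    fp = len(pred) - tp
    fn = len(nat) - tp
    n = target_length
    universe = (n - CONTACT_MIN_SEPARATION) * (n - CONTACT_MIN_SEPARATION + 1) // 2
    tn = max(universe - tp - fp - fn, 0)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
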