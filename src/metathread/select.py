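"""Template selection: decide from per-method threading scores whether a
template is structurally related to the target (TM-score >= 0.4).

Heterogeneous score scales (Z-scores, E-values, calibrated probabilities)
are normalised into one feature vector per template, with explicit
presence-mask features because a method failing to report a template is
itself informative.  A Gaussian-kernel support-vector classifier with
probability calibration is trained and evaluated under 2-fold
cross-validation; hyperparameters are grid-searched inside the training
folds only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from metathread.io_model import TargetSequence, ThreadingHit
from metathread.metrics import TM_SIGNIFICANCE

#: Templates more sequence-similar to the target than this (percent identity)
#: are excluded from training, evaluation and modeling.
SEQID_EXCLUSION = 40.0

#: E-values are floored before the log transform.
EVALUE_FLOOR = 1e-180

#: Hyperparameter grid for the Gaussian-kernel SVC.
SVC_GRID = {"C": [0.1, 1.0, 10.0], "gamma": [0.01, 0.1, 1.0]}


@dataclass
class TemplateFeatureVector:
    """Per-template normalized method scores plus a presence mask."""

    template_id: str
    scores: np.ndarray  # one standardized score per roster method
    mask: np.ndarray  # True where the method reported this template

    def as_row(self) -> np.ndarray:
        """Classifier input: scores followed by mask indicator features."""
        return np.concatenate([self.scores, self.mask.astype(float)])


@dataclass
class SelectionResult:
    template_id: str
    probability: float
    predicted_related: bool


def transform_raw_score(raw: float, score_type: str) -> float:
    """Map a raw method score onto a higher-is-better real scale."""
    if score_type == "zscore":
        return float(raw)
    if score_type == "evalue":
        return -math.log10(max(raw, EVALUE_FLOOR))
    if score_type == "probability":
        return float(raw)
    raise ValueError(f"unknown score_type {score_type!r}")


def normalize_scores(
    hits: Iterable[ThreadingHit], roster: Sequence[str]
) -> dict[str, TemplateFeatureVector]:
    """Feature vectors for every template reported by at least one method.

    Scores are mapped onto common higher-is-better scales (E-values via
    -log10), then each method column is standardized over the reported
    templates (a zero-variance column standardizes to all-zero).  Missing
    (method, template) entries become 0 after standardization with the mask
    bit cleared.  Duplicate hits from one method are de-duplicated (first
    kept).
    """
    roster = list(roster)
    m_index = {m: k for k, m in enumerate(roster)}
    raw: dict[str, dict[str, float]] = {}
    for hit in hits:
        if hit.method not in m_index:
            raise ValueError(f"hit from method {hit.method!r} not in roster {roster}")
        per_tpl = raw.setdefault(hit.method, {})
        if hit.template_id not in per_tpl:  # idempotent de-duplication
            per_tpl[hit.template_id] = transform_raw_score(hit.raw_score, hit.score_type)
    template_ids = sorted({t for per in raw.values() for t in per})
    n, m = len(template_ids), len(roster)
    scores = np.zeros((n, m))
    mask = np.zeros((n, m), dtype=bool)
    for method, per_tpl in raw.items():
        j = m_index[method]
        vals = np.array([per_tpl.get(t, np.nan) for t in template_ids])
        present = ~np.isnan(vals)
        col = vals[present]
        sd = col.std()
        standardized = (col - col.mean()) / sd if sd > 0 else np.zeros(len(col))
        scores[present, j] = standardized
        mask[present, j] = True
    return {
        tid: TemplateFeatureVector(template_id=tid, scores=scores[i], mask=mask[i])
        for i, tid in enumerate(template_ids)
    }


def method_rank_quantile(
    hits: Iterable[ThreadingHit], roster: Sequence[str]
) -> dict[tuple[str, str], float]:
    """Within-target rank quantile of each (method, template) score in [0, 1].

    Serves as the per-method hit confidence consumed by the consensus
    aligner: 1 for a method's best-scoring template, approaching 0 for its
    worst, 0 for unreported templates.
    """
    by_method: dict[str, list[tuple[str, float]]] = {}
    for hit in hits:
        by_method.setdefault(hit.method, []).append(
            (hit.template_id, transform_raw_score(hit.raw_score, hit.score_type))
        )
    out: dict[tuple[str, str], float] = {}
    for method, entries in by_method.items():
        seen: dict[str, float] = {}
        for tid, s in entries:
            seen.setdefault(tid, s)
        ranked = sorted(seen.items(), key=lambda kv: (kv[1], kv[0]))
        n = len(ranked)
        for pos, (tid, _) in enumerate(ranked):
            out[(method, tid)] = (pos + 1) / n
    return out


# ---------------------------------------------------------------------------
# sequence identity and labelling
# ---------------------------------------------------------------------------

_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def sequence_identity(a: TargetSequence | str, b: TargetSequence | str) -> float:
    """Percent sequence identity from a global BLOSUM62 alignment
    (gap open 11, extend 1), normalised by the shorter sequence."""
    sa = a.residues if isinstance(a, TargetSequence) else a
    sb = b.residues if isinstance(b, TargetSequence) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(sa, sb)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a = sa[a0:a1]
        seg_b = sb[b0:b1]
        ident += sum(1 for x, y in zip(seg_a, seg_b) if x == y)
    return 100.0 * ident / min(len(sa), len(sb))


def label_templates(
    true_tm: dict[str, float],
    target_seq: TargetSequence | None = None,
    template_seqs: dict[str, str] | None = None,
    threshold: float = TM_SIGNIFICANCE,
    seqid_cutoff: float = SEQID_EXCLUSION,
) -> tuple[dict[str, bool], set[str]]:
    """Relatedness labels (TM >= threshold) and the excluded-template set.

    Templates whose sequence identity to the target exceeds ``seqid_cutoff``
    percent are excluded entirely (trivial homologues), mirroring the
    benchmark protocol applied at every modeling step.
    """
    excluded: set[str] = set()
    if target_seq is not None and template_seqs:
        for tid, seq in template_seqs.items():
            if tid in true_tm and sequence_identity(target_seq, seq) > seqid_cutoff:
                excluded.add(tid)
    labels = {tid: tm >= threshold for tid, tm in true_tm.items() if tid not in excluded}
    return labels, excluded


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


@dataclass
class SelectorModel:
    """Trained template-selection classifier (Gaussian-kernel SVC with
    probability calibration) plus its cross-validated evaluation output."""

    classifier: object  # calibrated Gaussian-kernel SVC
    roster: list[str]
    cv_probabilities: np.ndarray  # P(related), produced by the fold not containing the item
    fold_of_item: np.ndarray
    best_params: dict

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.classifier.predict_proba(features)[:, 1]


def _fit_fold(x: np.ndarray, y: np.ndarray, seed: int):
    from sklearn.calibration import CalibratedClassifierCV

    grid = GridSearchCV(
        SVC(kernel="rbf"),
        SVC_GRID,
        cv=StratifiedKFold(2, shuffle=True, random_state=seed),
        scoring="roc_auc",
    )
    grid.fit(x, y)
    clf = CalibratedClassifierCV(
        SVC(kernel="rbf", **grid.best_params_),
        cv=StratifiedKFold(3, shuffle=True, random_state=seed),
        ensemble=False,
    )
    clf.fit(x, y)
    return clf, grid.best_params_


def train_selector(
    features: np.ndarray,
    labels: Sequence[bool],
    folds: int = 2,
    seed: int = 0,
) -> SelectorModel:
    """Train the meta-classifier with ``folds``-fold cross-validation.

    Per-item probabilities come only from the fold model that did not see
    the item.  Raises if any fold ends up single-class (re-split with a
    different seed or more data).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("features must be 2-D and aligned with labels")
    if y.min() == y.max():
        raise ValueError("training data contains a single class")
    splitter = StratifiedKFold(folds, shuffle=True, random_state=seed)
    cv_prob = np.zeros(len(y))
    fold_of = np.zeros(len(y), dtype=int)
    for k, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        ytr = y[train_idx]
        if ytr.min() == ytr.max():
            raise ValueError(
                f"fold {k} is single-class; re-split with a different seed"
            )
        clf, _ = _fit_fold(x[train_idx], ytr, seed + k + 1)
        cv_prob[test_idx] = clf.predict_proba(x[test_idx])[:, 1]
        fold_of[test_idx] = k
    final, params = _fit_fold(x, y, seed)
    return SelectorModel(
        classifier=final,
        roster=[],
        cv_probabilities=cv_prob,
        fold_of_item=fold_of,
        best_params=params,
    )


def select_templates(
    model: SelectorModel,
    feature_vectors: dict[str, TemplateFeatureVector],
    probability_cutoff: float = 0.5,
) -> list[SelectionResult]:
    """Score candidate templates and return them sorted by decreasing
    probability (ties broken by template id)."""
    if not feature_vectors:
        return []
    ids = sorted(feature_vectors)
    x = np.vstack([feature_vectors[t].as_row() for t in ids])
    probs = model.predict_proba(x)
    results = [
        SelectionResult(
            template_id=tid,
            probability=float(p),
            predicted_related=bool(p >= probability_cutoff),
        )
        for tid, p in zip(ids, probs)
    ]
    results.sort(key=lambda r: (-r.probability, r.template_id))
    return results
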