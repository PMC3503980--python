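"""Model ranking and confidence estimation.

Candidate models of a target are ranked with a pairwise-transform linear
ranking machine (same-target model pairs ordered by true TM-score become
classification examples on feature differences) and each model's TM-score
to native is estimated with Gaussian-kernel support-vector regression,
clipped to [0, 1].

Feature set per model: mean consensus-alignment confidence (Alignment),
mean alignment coverage (Coverage), secondary-structure agreement with a
provided 3-state prediction (PSIPRED-style match fraction), a burial
log-odds score, a secondary-structure preference log-odds score, and the
cluster fraction or mean TM-score to templates depending on provenance.
External statistical-potential columns (DOPE, dFire, GA341, clustering
coefficients) are accepted as optional extra features and excluded from the
model when absent, never imputed silently.

The burial and secondary-structure scores are this package's own
definitions: mean log-odds of each residue type's observed burial state
(CA neighbour count within 10 A, three bins) or assigned secondary
structure against library-derived propensities.  They are isolated behind
one interface so alternative formulations can replace them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR, LinearSVC

from metathread.io_model import RANK_FEATURES, PairAlignment, RankFeatureVector, StructureCoords
from metathread.metrics import tm_score

SS_STATES = "HEC"
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: CA neighbour radius (A) and bin edges for the burial state.
BURIAL_RADIUS = 10.0
BURIAL_BIN_EDGES = (8, 14)  # <8 exposed, 8-13 intermediate, >=14 buried

#: Same-target training pairs need a TM gap above this to count (near-ties
#: are label noise).
RANK_PAIR_MIN_GAP = 0.01


# ---------------------------------------------------------------------------
# geometric secondary-structure assignment
# ---------------------------------------------------------------------------


def assign_secondary_structure(structure: StructureCoords) -> str:
    """3-state secondary structure from CA geometry.

    Helix: compact i..i+3 span (CA(i)-CA(i+3) under 6 A); strand: locally
    extended (CA(i)-CA(i+2) over 6.2 A and CA(i)-CA(i+3) over 8.5 A);
    otherwise coil.  Window votes are pooled per residue; deterministic.
    """
    xyz = structure.ca_array()
    n = len(xyz)
    votes = [{"H": 0, "E": 0, "C": 0} for _ in range(n)]
    for i in range(n - 3):
        d13 = np.linalg.norm(xyz[i + 3] - xyz[i])
        d12 = np.linalg.norm(xyz[i + 2] - xyz[i])
        if d13 < 6.0:
            state = "H"
        elif d12 > 6.2 and d13 > 8.5:
            state = "E"
        else:
            state = "C"
        for k in range(i, i + 4):
            votes[k][state] += 1
    out = []
    for v in votes:
        best = max(v.values())
        # tie order favours the regular states
        state = next(s for s in "HEC" if v[s] == best)
        out.append(state if best > 0 else "C")
    return "".join(out)


def burial_bins(structure: StructureCoords) -> np.ndarray:
    """Burial state per residue: CA neighbour count within 10 A, 3 bins."""
    xyz = structure.ca_array()
    tree = cKDTree(xyz)
    counts = np.array([len(tree.query_ball_point(p, BURIAL_RADIUS)) - 1 for p in xyz])
    return np.digitize(counts, BURIAL_BIN_EDGES)


# ---------------------------------------------------------------------------
# propensity tables and the two substitute scores
# ---------------------------------------------------------------------------


@dataclass
class PropensityTable:
    """Log-odds of residue type given a discrete state vs background."""

    log_odds: np.ndarray  # (20, n_states)

    def score(self, aa_indices: np.ndarray, states: np.ndarray) -> float:
        ok = aa_indices >= 0
        if not np.any(ok):
            return 0.0
        return float(self.log_odds[aa_indices[ok], states[ok]].mean())


def _propensities(aa_idx_all: list[np.ndarray], states_all: list[np.ndarray], n_states: int):
    counts = np.ones((20, n_states))  # add-one smoothing
    for aa_idx, states in zip(aa_idx_all, states_all):
        for a, s in zip(aa_idx, states):
            if a >= 0:
                counts[a, s] += 1
    p_joint = counts / counts.sum()
    p_aa = p_joint.sum(axis=1, keepdims=True)
    p_state = p_joint.sum(axis=0, keepdims=True)
    return PropensityTable(log_odds=np.log(p_joint / (p_aa * p_state)))


def _aa_indices(sequence: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, -1) for a in sequence])


def derive_propensities(
    structures: Iterable[StructureCoords],
) -> tuple[PropensityTable, PropensityTable]:
    """(burial, secondary-structure) propensity tables from a library of
    native structures."""
    aa_all, burial_all, ss_all = [], [], []
    for s in structures:
        aa_all.append(_aa_indices(s.sequence))
        burial_all.append(burial_bins(s))
        ss_all.append(
            np.array([SS_STATES.index(c) for c in assign_secondary_structure(s)])
        )
    burial_table = _propensities(aa_all, burial_all, 3)
    ss_table = _propensities(aa_all, ss_all, 3)
    return burial_table, ss_table


def burial_score(structure: StructureCoords, table: PropensityTable) -> float:
    """Mean burial log-odds of the model; higher is more native-like."""
    if len(structure) < 10:
        raise ValueError("burial score requires at least 10 residues")
    return table.score(_aa_indices(structure.sequence), burial_bins(structure))


def secstr_score(structure: StructureCoords, table: PropensityTable) -> float:
    """Mean secondary-structure preference log-odds of the model."""
    if len(structure) < 10:
        raise ValueError("secondary-structure score requires at least 10 residues")
    states = np.array([SS_STATES.index(c) for c in assign_secondary_structure(structure)])
    return table.score(_aa_indices(structure.sequence), states)


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def assemble_features(
    model_id: str,
    model: StructureCoords,
    alignments: Mapping[str, PairAlignment],
    templates: Mapping[str, StructureCoords],
    predicted_ss: str,
    burial_table: PropensityTable,
    secstr_table: PropensityTable,
    provenance: str = "cluster-based",
    cluster_fraction: float | None = None,
    external: Mapping[str, float] | None = None,
) -> RankFeatureVector:
    """Complete per-model feature vector.

    ``fraction_or_tmscore`` is the cluster fraction for cluster-based model
    sets and the mean TM-score of the model to its templates (over the
    consensus alignments) for trajectory-based sets.  A missing required
    ingredient raises with its name.
    """
    if not alignments:
        raise ValueError("assemble_features: no consensus alignments provided")
    if len(predicted_ss) != len(model):
        raise ValueError("assemble_features: predicted_ss length mismatch")
    alignment_conf = float(
        np.mean([a.mean_confidence for a in alignments.values()])
    )
    coverage = float(np.mean([a.coverage for a in alignments.values()]))
    model_ss = assign_secondary_structure(model)
    psipred_match = float(
        np.mean([a == b for a, b in zip(model_ss, predicted_ss)])
    )
    if provenance == "cluster-based":
        if cluster_fraction is None:
            raise ValueError("assemble_features: cluster_fraction required")
        fraction_or_tm = float(cluster_fraction)
    elif provenance == "trajectory-based":
        tms = []
        for tid, aln in alignments.items():
            if tid not in templates:
                raise ValueError(f"assemble_features: template {tid} structure missing")
            if len(aln.pairs) >= 5:
                tms.append(tm_score(model, templates[tid], pairs=aln.pairs,
                                    norm_length=len(model)))
        if not tms:
            raise ValueError("assemble_features: no usable template alignments")
        fraction_or_tm = float(np.mean(tms))
    else:
        raise ValueError(f"unknown provenance {provenance!r}")
    return RankFeatureVector(
        model_id=model_id,
        alignment_conf=alignment_conf,
        coverage=coverage,
        psipred_match=psipred_match,
        burial=burial_score(model, burial_table),
        secstr=secstr_score(model, secstr_table),
        fraction_or_tmscore=fraction_or_tm,
        external=dict(external or {}),
    )


# ---------------------------------------------------------------------------
# ranking machine and confidence regressor
# ---------------------------------------------------------------------------


@dataclass
class RankerModel:
    """Linear ranking machine on standardized features."""

    scaler: StandardScaler
    weights: np.ndarray
    feature_columns: list[str]

    def score(self, x: np.ndarray) -> np.ndarray:
        return self.scaler.transform(np.asarray(x, dtype=float)) @ self.weights


@dataclass
class ConfidenceModel:
    """SVR estimate of the TM-score to native, clipped to [0, 1]."""

    scaler: StandardScaler
    svr: SVR
    feature_columns: list[str]

    def predict(self, x: np.ndarray) -> np.ndarray:
        raw = self.svr.predict(self.scaler.transform(np.asarray(x, dtype=float)))
        return np.clip(raw, 0.0, 1.0)


def _pairwise_examples(
    x: np.ndarray, tm: np.ndarray, groups: np.ndarray, min_gap: float
) -> tuple[np.ndarray, np.ndarray]:
    """Anti-symmetric feature-difference examples from same-target pairs."""
    rows, labels = [], []
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ia, ib = idx[a], idx[b]
                gap = tm[ia] - tm[ib]
                if abs(gap) <= min_gap:
                    continue
                diff = x[ia] - x[ib]
                rows.append(diff)
                labels.append(1 if gap > 0 else 0)
                rows.append(-diff)
                labels.append(0 if gap > 0 else 1)
    return np.array(rows), np.array(labels)


def train_ranker(
    features: pd.DataFrame,
    tm_column: str = "true_tm",
    group_column: str = "target_id",
    feature_columns: Sequence[str] | None = None,
    folds: int = 2,
    seed: int = 0,
    min_gap: float = RANK_PAIR_MIN_GAP,
) -> tuple[RankerModel, np.ndarray]:
    """Pairwise-transform ranking machine with grouped cross-validation.

    Targets (groups) are split into folds; each row's cross-validated
    ranking score comes from the fold model that did not train on its
    target.  A target with a single model contributes no pairs (logged).
    Returns the final model and the per-row cross-validated scores.
    """
    import logging

    logger = logging.getLogger(__name__)
    cols = list(feature_columns or RANK_FEATURES)
    x = features[cols].to_numpy(dtype=float)
    tm = features[tm_column].to_numpy(dtype=float)
    groups = features[group_column].to_numpy()
    for g in np.unique(groups):
        if np.sum(groups == g) < 2:
            logger.info("target %s has a single model; contributes no pairs", g)

    def fit(train_mask: np.ndarray) -> RankerModel:
        scaler = StandardScaler().fit(x[train_mask])
        xs = scaler.transform(x[train_mask])
        diffs, labels = _pairwise_examples(
            xs, tm[train_mask], groups[train_mask], min_gap
        )
        if len(diffs) == 0:
            raise ValueError("no usable training pairs (all targets single-model?)")
        clf = LinearSVC(C=1.0, fit_intercept=False, random_state=seed)
        clf.fit(diffs, labels)
        return RankerModel(scaler=scaler, weights=clf.coef_.ravel(), feature_columns=cols)

    cv_scores = np.zeros(len(x))
    rng = np.random.default_rng(seed)
    unique_groups = np.array(sorted(np.unique(groups)))
    perm = rng.permutation(len(unique_groups))
    for k in range(folds):
        test_groups = set(unique_groups[perm[k::folds]])
        test_mask = np.isin(groups, list(test_groups))
        model_k = fit(~test_mask)
        cv_scores[test_mask] = model_k.score(x[test_mask])
    final = fit(np.ones(len(x), dtype=bool))
    return final, cv_scores


def train_confidence(
    features: pd.DataFrame,
    tm_column: str = "true_tm",
    group_column: str = "target_id",
    feature_columns: Sequence[str] | None = None,
    folds: int = 2,
    seed: int = 0,
) -> tuple[ConfidenceModel, np.ndarray, float]:
    """Gaussian-kernel SVR of TM-score on features, grouped ``folds``-fold CV.

    Returns the final model, per-row cross-validated predictions (clipped to
    [0, 1]) and the held-out Pearson correlation.
    """
    cols = list(feature_columns or RANK_FEATURES)
    x = features[cols].to_numpy(dtype=float)
    tm = features[tm_column].to_numpy(dtype=float)
    groups = features[group_column].to_numpy()

    def fit(train_mask: np.ndarray) -> ConfidenceModel:
        from sklearn.model_selection import GridSearchCV, KFold

        scaler = StandardScaler().fit(x[train_mask])
        grid = GridSearchCV(
            SVR(kernel="rbf", epsilon=0.02),
            {"C": [1.0, 10.0], "gamma": [0.003, 0.01, 0.1]},
            cv=KFold(2, shuffle=True, random_state=seed),
            scoring="r2",
        )
        grid.fit(scaler.transform(x[train_mask]), tm[train_mask])
        return ConfidenceModel(
            scaler=scaler, svr=grid.best_estimator_, feature_columns=cols
        )

    cv_pred = np.zeros(len(x))
    rng = np.random.default_rng(seed)
    unique_groups = np.array(sorted(np.unique(groups)))
    perm = rng.permutation(len(unique_groups))
    for k in range(folds):
        test_groups = set(unique_groups[perm[k::folds]])
        test_mask = np.isin(groups, list(test_groups))
        model_k = fit(~test_mask)
        cv_pred[test_mask] = model_k.predict(x[test_mask])
    cc = float(pearsonr(cv_pred, tm)[0])
    final = fit(np.ones(len(x), dtype=bool))
    return final, cv_pred, cc


@dataclass
class RankOutcome:
    ordering: list[str]
    estimated_tm: dict[str, float]


def rank_models(
    features: pd.DataFrame,
    ranker: RankerModel,
    regressor: ConfidenceModel,
    id_column: str = "model_id",
) -> RankOutcome:
    """Rank a target's models: by ranking score, ties by estimated TM-score
    then model id.  Empty input yields an empty outcome."""
    if len(features) == 0:
        return RankOutcome(ordering=[], estimated_tm={})
    x = features[ranker.feature_columns].to_numpy(dtype=float)
    scores = ranker.score(x)
    est = regressor.predict(features[regressor.feature_columns].to_numpy(dtype=float))
    ids = features[id_column].tolist()
    order = sorted(
        range(len(ids)), key=lambda k: (-scores[k], -est[k], ids[k])
    )
    return RankOutcome(
        ordering=[ids[k] for k in order],
        estimated_tm={ids[k]: float(est[k]) for k in range(len(ids))},
    )


def best_model_rank_curve(
    features: pd.DataFrame,
    scores: np.ndarray,
    tm_column: str = "true_tm",
    group_column: str = "target_id",
    max_rank: int = 5,
) -> np.ndarray:
    """Fraction of targets whose best model lands at each rank (1..max_rank)
    when models are ordered by ``scores`` (descending)."""
    tm = features[tm_column].to_numpy(dtype=float)
    groups = features[group_column].to_numpy()
    counts = np.zeros(max_rank)
    n_groups = 0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            continue
        n_groups += 1
        order = idx[np.argsort(-scores[idx], kind="stable")]
        best = idx[np.argmax(tm[idx])]
        rank = int(np.flatnonzero(order == best)[0])
        if rank < max_rank:
            counts[rank] += 1
    return counts / max(n_groups, 1)
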