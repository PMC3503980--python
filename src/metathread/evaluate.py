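"""Stage-level evaluation on labelled (synthetic) benchmarks.

Each evaluator runs one pipeline stage under 2-fold cross-validation over
targets and measures it against the benchmark's ground truth: ROC/AUC for
template selection, alignment MCC distributions for the consensus stage,
contact TPR/FPR/MCC for the contact stage, and rank-retrieval curves plus
confidence correlations for the ranking stage.  Every reported number is
recomputable from the stage outputs the evaluators return.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from metathread.consensus import (
    DEFAULT_GAP_PENALTY,
    build_alignment_training,
    consensus_alignment,
    train_alignment_nb,
)
from metathread.contacts import (
    contact_feature_table,
    derive_pair_potential,
    select_threshold_by_mcc,
    train_contact_svc,
)
from metathread.io_model import PairAlignment
from metathread.metrics import TM_SIGNIFICANCE, extract_contacts, alignment_mcc, roc_curve, tpr_at_fpr
from metathread.ranking import (
    best_model_rank_curve,
    train_confidence,
    train_ranker,
)
from metathread.select import (
    label_templates,
    method_rank_quantile,
    normalize_scores,
    train_selector,
)
from metathread.synthetic import SyntheticBenchmark, make_rank_benchmark

MISSING_SCORE = -10.0  # single-method ROC sentinel for unreported templates


# ---------------------------------------------------------------------------
# template selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionEvaluation:
    auc_meta: float
    auc_by_method: dict[str, float]
    probability_of: dict[tuple[str, str], float]  # cross-validated P(related)
    label_of: dict[tuple[str, str], bool]
    excluded: set[tuple[str, str]] = field(default_factory=set)

    @property
    def best_single_auc(self) -> float:
        return max(self.auc_by_method.values())


def evaluate_template_selection(
    bench: SyntheticBenchmark, seed: int = 0, seqid_filter: bool = True
) -> SelectionEvaluation:
    """Cross-validated meta-classifier vs single-method score ROC.

    Templates above the sequence-identity exclusion cutoff are dropped
    before training and evaluation, as in every other stage.
    """
    roster = [m.name for m in bench.methods]
    keys: list[tuple[str, str]] = []
    rows, labels = [], []
    method_scores: dict[str, list[float]] = {m: [] for m in roster}
    excluded_keys: set[tuple[str, str]] = set()
    for tid in bench.target_ids():
        tgt = bench.targets[tid]
        fvs = normalize_scores(bench.hits[tid], roster)
        true_tm = {qid: tgt.templates[qid].true_tm for qid in fvs}
        lbls, excluded = label_templates(
            true_tm,
            target_seq=tgt.sequence if seqid_filter else None,
            template_seqs={qid: tgt.templates[qid].structure.sequence for qid in fvs}
            if seqid_filter
            else None,
        )
        excluded_keys.update((tid, qid) for qid in excluded)
        for qid in sorted(lbls):
            keys.append((tid, qid))
            rows.append(fvs[qid].as_row())
            labels.append(lbls[qid])
            for k, m in enumerate(roster):
                fv = fvs[qid]
                method_scores[m].append(
                    fv.scores[k] if fv.mask[k] else MISSING_SCORE
                )
    x = np.vstack(rows)
    y = np.array(labels, dtype=bool)
    model = train_selector(x, y, folds=2, seed=seed)
    _, _, auc_meta = roc_curve(model.cv_probabilities, y)
    auc_by_method = {}
    for m in roster:
        _, _, auc = roc_curve(np.array(method_scores[m]), y)
        auc_by_method[m] = auc
    return SelectionEvaluation(
        auc_meta=auc_meta,
        auc_by_method=auc_by_method,
        probability_of={k: float(p) for k, p in zip(keys, model.cv_probabilities)},
        label_of={k: bool(v) for k, v in zip(keys, y)},
        excluded=excluded_keys,
    )


# ---------------------------------------------------------------------------
# consensus alignments
# ---------------------------------------------------------------------------


@dataclass
class ConsensusEvaluation:
    consensus_mcc_mean: float
    method_mcc_mean: dict[str, float]
    alignments: dict[tuple[str, str], PairAlignment]
    consensus_mcc_of: dict[tuple[str, str], float]
    fold_of_target: dict[str, int]

    @property
    def mean_single_method_mcc(self) -> float:
        return float(np.mean(list(self.method_mcc_mean.values())))

    @property
    def best_single_method_mcc(self) -> float:
        return max(self.method_mcc_mean.values())


def _split_targets(target_ids: list[str], folds: int, seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(target_ids))
    return {target_ids[perm[k]]: k % folds for k in range(len(target_ids))}


def evaluate_consensus_alignment(
    bench: SyntheticBenchmark,
    seed: int = 0,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    max_train_pairs_per_fold: int = 80,
) -> ConsensusEvaluation:
    """Consensus alignment MCC vs each mock method's own alignments.

    The Naive-Bayes aligner scoring a target's alignments is always trained
    on the other cross-validation fold's targets.
    """
    roster = [m.name for m in bench.methods]
    fold_of = _split_targets(bench.target_ids(), 2, seed)
    rng = np.random.default_rng(seed + 1)

    # (hits, confidences, reference set, dims) per target/template pair
    pair_data: dict[tuple[str, str], tuple] = {}
    conf_of_target: dict[str, dict] = {}
    for tid in bench.target_ids():
        tgt = bench.targets[tid]
        quantiles = method_rank_quantile(bench.hits[tid], roster)
        conf_of_target[tid] = quantiles
        by_template: dict[str, list] = {}
        for hit in bench.hits[tid]:
            by_template.setdefault(hit.template_id, []).append(hit)
        for qid, tpl_hits in by_template.items():
            tpl = tgt.templates[qid]
            confs = {h.method: quantiles[(h.method, qid)] for h in tpl_hits}
            pair_data[(tid, qid)] = (
                tpl_hits,
                confs,
                set(tpl.reference_pairs),
                len(tgt.native),
                len(tpl.structure),
            )

    nb_of_fold = {}
    for fold in (0, 1):
        train_keys = [k for k in sorted(pair_data) if fold_of[k[0]] != fold]
        if len(train_keys) > max_train_pairs_per_fold:
            pick = rng.choice(len(train_keys), size=max_train_pairs_per_fold, replace=False)
            train_keys = [train_keys[i] for i in sorted(pick)]
        ind, bins, y = build_alignment_training(
            [pair_data[k] for k in train_keys], roster, rng=rng
        )
        nb_of_fold[fold] = train_alignment_nb(ind, bins, y, roster)

    alignments: dict[tuple[str, str], PairAlignment] = {}
    consensus_mcc: dict[tuple[str, str], float] = {}
    method_mccs: dict[str, list[float]] = {m: [] for m in roster}
    for (tid, qid), (tpl_hits, confs, ref_set, lt, lq) in sorted(pair_data.items()):
        nb = nb_of_fold[fold_of[tid]]
        aln = consensus_alignment(
            nb, tpl_hits, tid, qid, lt, lq, confidences=confs, gap_penalty=gap_penalty
        )
        alignments[(tid, qid)] = aln
        reference = PairAlignment(
            target_id=tid,
            template_id=qid,
            pairs=sorted(ref_set),
            per_pair_confidence=[1.0] * len(ref_set),
            target_length=lt,
            template_length=lq,
        )
        consensus_mcc[(tid, qid)] = alignment_mcc(aln, reference)
        for hit in tpl_hits:
            predicted = PairAlignment(
                target_id=tid,
                template_id=qid,
                pairs=list(hit.alignment),
                per_pair_confidence=[1.0] * len(hit.alignment),
                target_length=lt,
                template_length=lq,
            )
            method_mccs[hit.method].append(alignment_mcc(predicted, reference))
    return ConsensusEvaluation(
        consensus_mcc_mean=float(np.mean(list(consensus_mcc.values()))),
        method_mcc_mean={m: float(np.mean(v)) for m, v in method_mccs.items() if v},
        alignments=alignments,
        consensus_mcc_of=consensus_mcc,
        fold_of_target=fold_of,
    )


# ---------------------------------------------------------------------------
# contact stage
# ---------------------------------------------------------------------------


@dataclass
class ContactEvaluation:
    tpr_at_fpr05: float
    baseline_tpr: float
    baseline_fpr: float
    best_threshold: float
    best_mcc: float
    auc: float
    probabilities: np.ndarray  # fold 0 targets (sorted), then fold 1
    labels: np.ndarray
    frac_feature: np.ndarray
    pairs_of_target: dict[str, np.ndarray] = field(default_factory=dict)
    fold_of_target: dict[str, int] = field(default_factory=dict)


def evaluate_contact_stage(
    bench: SyntheticBenchmark,
    seed: int = 0,
    selection: SelectionEvaluation | None = None,
    consensus: ConsensusEvaluation | None = None,
    selection_cutoff: float = 0.5,
) -> ContactEvaluation:
    """Contact prediction from consensus alignments + selected templates.

    The pair potential, the contact SVC and all upstream models are trained
    on the cross-validation fold not containing the evaluated target.  The
    majority-vote baseline predicts a contact when more than half of the
    selected templates vote for it.
    """
    selection = selection or evaluate_template_selection(bench, seed)
    consensus = consensus or evaluate_consensus_alignment(bench, seed)
    fold_of = consensus.fold_of_target

    potential_of_fold = {}
    for fold in (0, 1):
        train_natives = [
            bench.targets[tid].native
            for tid in bench.target_ids()
            if fold_of[tid] != fold
        ]
        potential_of_fold[fold] = derive_pair_potential(train_natives)

    template_contacts_cache: dict[str, set] = {}

    def target_features(tid: str):
        tgt = bench.targets[tid]
        selected = {
            qid: selection.probability_of[(tid, qid)]
            for qid in tgt.templates
            if selection.probability_of.get((tid, qid), 0.0) >= selection_cutoff
        }
        alns = {
            qid: consensus.alignments[(tid, qid)]
            for qid in selected
            if (tid, qid) in consensus.alignments
        }
        if not alns:
            return None
        for qid in alns:
            if qid not in template_contacts_cache:
                template_contacts_cache[qid] = extract_contacts(
                    tgt.templates[qid].structure
                )
        pairs, feats = contact_feature_table(
            tgt.sequence.residues,
            alns,
            {qid: template_contacts_cache[qid] for qid in alns},
            selected,
            potential_of_fold[fold_of[tid]],
        )
        native = {(c.i, c.j) for c in tgt.contacts}
        labels = np.array([(int(i), int(j)) in native for i, j in pairs])
        return pairs, feats, labels

    per_target = {}
    for tid in bench.target_ids():
        res = target_features(tid)
        if res is not None:
            per_target[tid] = res

    all_probs, all_labels, all_frac = [], [], []
    for fold in (0, 1):
        train_x = np.vstack(
            [per_target[t][1] for t in sorted(per_target) if fold_of[t] != fold]
        )
        train_y = np.concatenate(
            [per_target[t][2] for t in sorted(per_target) if fold_of[t] != fold]
        )
        model = train_contact_svc(train_x, train_y, seed=seed + fold)
        for t in sorted(per_target):
            if fold_of[t] != fold:
                continue
            _, feats, labels = per_target[t]
            all_probs.append(model.predict_proba(feats))
            all_labels.append(labels)
            all_frac.append(feats[:, 0])
    probs = np.concatenate(all_probs)
    labels = np.concatenate(all_labels)
    frac = np.concatenate(all_frac)
    pairs_of_target = {t: per_target[t][0] for t in per_target}
    _, _, auc = roc_curve(probs, labels)
    tpr05 = tpr_at_fpr(probs, labels, 0.05)
    baseline_pred = frac > 0.5
    tp = int(np.sum(baseline_pred & labels))
    fp = int(np.sum(baseline_pred & ~labels))
    fn = int(np.sum(~baseline_pred & labels))
    tn = int(np.sum(~baseline_pred & ~labels))
    baseline_tpr = tp / (tp + fn) if tp + fn else 0.0
    baseline_fpr = fp / (fp + tn) if fp + tn else 0.0
    threshold, mcc = select_threshold_by_mcc(probs, labels)
    return ContactEvaluation(
        tpr_at_fpr05=float(tpr05),
        baseline_tpr=float(baseline_tpr),
        baseline_fpr=float(baseline_fpr),
        best_threshold=threshold,
        best_mcc=mcc,
        auc=auc,
        probabilities=probs,
        labels=labels,
        frac_feature=frac,
        pairs_of_target=pairs_of_target,
        fold_of_target=fold_of,
    )


# ---------------------------------------------------------------------------
# ranking / confidence
# ---------------------------------------------------------------------------


@dataclass
class RankingEvaluation:
    rank1_rate: float
    rank1_by_feature: dict[str, float]
    confidence_cc: float
    cc_by_feature: dict[str, float]
    rank_curve: np.ndarray


def evaluate_ranking(
    seed: int = 0, n_targets: int = 60, models_per_target: int = 8
) -> RankingEvaluation:
    """Ranking and confidence recovery on a synthetic decoy feature set."""
    from scipy.stats import pearsonr

    table = make_rank_benchmark(
        n_targets=n_targets, models_per_target=models_per_target, seed=seed
    )
    feature_cols = [
        "alignment_conf",
        "coverage",
        "psipred_match",
        "burial",
        "secstr",
        "fraction_or_tmscore",
    ]
    _, cv_scores = train_ranker(table, feature_columns=feature_cols, seed=seed)
    curve = best_model_rank_curve(table, cv_scores)
    rank1_by_feature = {}
    for col in feature_cols:
        curve_f = best_model_rank_curve(table, table[col].to_numpy(dtype=float))
        rank1_by_feature[col] = float(curve_f[0])
    _, _, cc = train_confidence(table, feature_columns=feature_cols, seed=seed)
    tm = table["true_tm"].to_numpy(dtype=float)
    cc_by_feature = {
        col: float(pearsonr(table[col].to_numpy(dtype=float), tm)[0])
        for col in feature_cols
    }
    return RankingEvaluation(
        rank1_rate=float(curve[0]),
        rank1_by_feature=rank1_by_feature,
        confidence_cc=cc,
        cc_by_feature=cc_by_feature,
        rank_curve=curve,
    )
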