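"""End-to-end orchestration: simulate/train -> select -> align -> contacts
-> rank, with reproducible run directories and an evaluation report.

``run_pipeline`` consumes a benchmark directory (as written by
:func:`metathread.synthetic.write_benchmark`), executes every stage under
cross-validation and persists one report per stage plus a manifest carrying
the full configuration, its hash and the seed.  Re-running with the same
inputs and configuration reproduces every report byte for byte.

``evaluate_run`` recomputes all quality metrics purely from the persisted
stage reports and the benchmark's ground-truth manifest — no hidden state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from metathread import __version__
from metathread.config import PipelineConfig
from metathread.evaluate import (
    evaluate_consensus_alignment,
    evaluate_contact_stage,
    evaluate_template_selection,
)
from metathread.io_model import RANK_FEATURES, write_alignments, read_alignments
from metathread.metrics import mcc_from_counts, roc_curve
from metathread.ranking import (
    assemble_features,
    derive_propensities,
    assign_secondary_structure,
    train_confidence,
    train_ranker,
)
from metathread.synthetic import SyntheticBenchmark, load_benchmark

logger = logging.getLogger(__name__)


def _float(x: float) -> str:
    return repr(float(x))


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, out_dir: str | Path
) -> Path:
    """Run every stage on a benchmark directory and persist the reports.

    Writes ``selection.tsv``, ``alignments.tsv``, ``contacts.tsv``,
    ``ranks.tsv`` and ``manifest.json`` into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bench = load_benchmark(input_dir)
    seed = config.seed

    # --- stage 1: template selection -----------------------------------
    selection = evaluate_template_selection(bench, seed=seed)
    logger.info(
        "selection: %d candidates scored, %d excluded by sequence identity",
        len(selection.probability_of), len(selection.excluded),
    )
    with open(out / "selection.tsv", "w") as fh:
        fh.write("# target_id\ttemplate_id\tprobability\tpredicted_related\n")
        for (tid, qid) in sorted(selection.probability_of):
            p = selection.probability_of[(tid, qid)]
            fh.write(
                f"{tid}\t{qid}\t{_float(p)}\t{int(p >= config.selection_cutoff)}\n"
            )

    # --- stage 2: consensus alignments ----------------------------------
    consensus = evaluate_consensus_alignment(
        bench, seed=seed, gap_penalty=config.gap_penalty
    )
    write_alignments(
        out / "alignments.tsv",
        [consensus.alignments[k] for k in sorted(consensus.alignments)],
    )

    # --- stage 3: contacts ----------------------------------------------
    contact = evaluate_contact_stage(
        bench,
        seed=seed,
        selection=selection,
        consensus=consensus,
        selection_cutoff=config.selection_cutoff,
    )
    _write_contact_report(out / "contacts.tsv", bench, contact, config)

    # --- stage 4: ranking -----------------------------------------------
    table = _decoy_feature_table(bench, selection, consensus, config)
    if table is not None and table["target_id"].nunique() >= 2:
        ranker, cv_scores = train_ranker(table, folds=config.folds, seed=seed)
        _, cv_pred, cc = train_confidence(table, folds=config.folds, seed=seed)
        table = table.assign(rank_score=cv_scores, estimated_tm=cv_pred)
        with open(out / "ranks.tsv", "w") as fh:
            cols = "\t".join(RANK_FEATURES)
            fh.write(f"# target_id\tmodel_id\trank\testimated_tm\t{cols}\n")
            for tid, group in table.groupby("target_id", sort=True):
                group = group.sort_values(
                    ["rank_score", "estimated_tm", "model_id"],
                    ascending=[False, False, True],
                )
                for rank, (_, r) in enumerate(group.iterrows(), start=1):
                    feats = "\t".join(_float(r[c]) for c in RANK_FEATURES)
                    fh.write(
                        f"{tid}\t{r['model_id']}\t{rank}\t{_float(r['estimated_tm'])}\t{feats}\n"
                    )
        logger.info("ranking: %d models across %d targets (held-out CC %.3f)",
                    len(table), table["target_id"].nunique(), cc)
    else:
        (out / "ranks.tsv").write_text("# target_id\tmodel_id\trank\testimated_tm\n")
        logger.warning("ranking skipped: fewer than 2 targets with usable models")

    # --- manifest --------------------------------------------------------
    config_dict = config.to_dict()
    config_blob = json.dumps(config_dict, sort_keys=True).encode()
    manifest = {
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": seed,
        "version": __version__,
        "input": str(Path(input_dir).name),
        "stages": ["selection", "alignments", "contacts", "ranks"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _n_candidate_pairs(n: int) -> int:
    return (n - 5) * (n - 4) // 2


def _write_contact_report(
    path: Path, bench: SyntheticBenchmark, contact, config: PipelineConfig
) -> None:
    with open(path, "w") as fh:
        fh.write("# target_id\ti\tj\tprobability\n")
        row = 0
        for tid, n_pairs, pairs in _contact_row_layout(bench, contact):
            probs = contact.probabilities[row : row + n_pairs]
            for (i, j), p in zip(pairs, probs):
                if p >= config.contact_threshold:
                    fh.write(f"{tid}\t{int(i)}\t{int(j)}\t{_float(p)}\n")
            row += n_pairs


def _contact_row_layout(bench: SyntheticBenchmark, contact):
    """Yield (target_id, n_rows, pairs) in the concatenation order used by
    the contact evaluator (fold 0 targets sorted, then fold 1)."""
    fold_of = contact.fold_of_target
    for fold in (0, 1):
        for tid in bench.target_ids():
            if fold_of.get(tid) != fold or tid not in contact.pairs_of_target:
                continue
            pairs = contact.pairs_of_target[tid]
            yield tid, len(pairs), pairs


def _decoy_feature_table(bench, selection, consensus, config: PipelineConfig):
    """Structure-derived ranking features for every benchmark decoy model."""
    natives = [bench.targets[t].native for t in bench.target_ids()]
    burial_table, ss_table = derive_propensities(natives)
    rows = []
    for tid in bench.target_ids():
        tgt = bench.targets[tid]
        selected = [
            qid
            for qid in sorted(tgt.templates)
            if selection.probability_of.get((tid, qid), 0.0) >= config.selection_cutoff
            and (tid, qid) in consensus.alignments
        ]
        if not selected:
            logger.warning("target %s: no selected templates; decoys unranked", tid)
            continue
        alns = {qid: consensus.alignments[(tid, qid)] for qid in selected}
        templates = {qid: tgt.templates[qid].structure for qid in selected}
        predicted_ss = assign_secondary_structure(tgt.native)
        for decoy in tgt.decoys:
            fv = assemble_features(
                model_id=decoy.id,
                model=decoy.structure,
                alignments=alns,
                templates=templates,
                predicted_ss=predicted_ss,
                burial_table=burial_table,
                secstr_table=ss_table,
                provenance="trajectory-based",
            )
            row = {"target_id": tid, "model_id": decoy.id, "true_tm": decoy.true_tm}
            row.update({name: getattr(fv, name) for name in RANK_FEATURES})
            rows.append(row)
    if not rows:
        return None
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evaluation of a persisted run
# ---------------------------------------------------------------------------


def evaluate_run(run_dir: str | Path, truth_dir: str | Path) -> dict[str, float]:
    """Quality metrics of a persisted run against benchmark ground truth.

    Every metric is computed from the stage report files alone; raises with
    the name of the first missing artefact.
    """
    run = Path(run_dir)
    with open(Path(truth_dir) / "manifest.json") as fh:
        truth = json.load(fh)

    for name in ("selection.tsv", "alignments.tsv", "contacts.tsv", "ranks.tsv"):
        if not (run / name).exists():
            raise FileNotFoundError(f"run directory lacks {name}")

    metrics: dict[str, float] = {}

    # selection AUC from persisted probabilities
    probs, labels = [], []
    with open(run / "selection.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            tid, qid, p, _ = line.rstrip("\n").split("\t")
            probs.append(float(p))
            labels.append(truth["targets"][tid]["templates"][qid]["true_tm"] >= 0.4)
    if len(set(labels)) == 2:
        _, _, auc = roc_curve(np.array(probs), np.array(labels))
        metrics["selection_auc"] = auc

    # alignment MCC distribution
    from metathread.io_model import PairAlignment
    from metathread.metrics import alignment_mcc

    mccs = []
    for aln in read_alignments(run / "alignments.tsv"):
        tinfo = truth["targets"][aln.target_id]["templates"][aln.template_id]
        ref = PairAlignment(
            target_id=aln.target_id,
            template_id=aln.template_id,
            pairs=[(int(t), int(q)) for t, q in tinfo["reference_pairs"]],
            per_pair_confidence=[1.0] * len(tinfo["reference_pairs"]),
            target_length=aln.target_length,
            template_length=aln.template_length,
        )
        mccs.append(alignment_mcc(aln, ref))
    if mccs:
        metrics["alignment_mcc_mean"] = float(np.mean(mccs))

    # contact confusion at the reporting threshold
    tp = fp = fn = tn = 0
    predicted: dict[str, set] = {}
    with open(run / "contacts.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            tid, i, j, _ = line.rstrip("\n").split("\t")
            predicted.setdefault(tid, set()).add((int(i), int(j)))
    for tid, entry in truth["targets"].items():
        native = {(min(i, j), max(i, j)) for i, j in entry["contacts"]}
        pred = predicted.get(tid, set())
        n = entry["length"]
        universe = _n_candidate_pairs(n)
        tp += len(pred & native)
        fp += len(pred - native)
        fn += len(native - pred)
        tn += universe - len(pred | native)
    if tp + fn:
        metrics["contact_tpr"] = tp / (tp + fn)
        metrics["contact_fpr"] = fp / (fp + tn) if fp + tn else 0.0
        metrics["contact_mcc"] = mcc_from_counts(tp, fp, tn, fn)

    # rank-1 retrieval and confidence correlation
    rows = []
    with open(run / "ranks.tsv") as fh:
        header = fh.readline().lstrip("# ").rstrip("\n").split("\t")
        for line in fh:
            rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    if rows:
        df = pd.DataFrame(rows)
        df["rank"] = df["rank"].astype(int)
        df["estimated_tm"] = df["estimated_tm"].astype(float)
        df["true_tm"] = [
            truth["targets"][t]["decoys"][m]
            for t, m in zip(df["target_id"], df["model_id"])
        ]
        hits = 0
        n_targets = 0
        for tid, group in df.groupby("target_id"):
            if len(group) < 2:
                continue
            n_targets += 1
            best = group.loc[group["true_tm"].idxmax()]
            if int(best["rank"]) == 1:
                hits += 1
        if n_targets:
            metrics["rank1_rate"] = hits / n_targets
        from scipy.stats import pearsonr

        if df["true_tm"].nunique() > 1:
            metrics["confidence_cc"] = float(
                pearsonr(df["estimated_tm"], df["true_tm"])[0]
            )
    return metrics


def write_metrics(metrics: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# metric\tvalue\n")
        for k in sorted(metrics):
            fh.write(f"{k}\t{metrics[k]:.6f}\n")
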