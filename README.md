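# metathread

A toolkit for the meta-threading layer of template-based protein structure
modeling.  Individual threading / fold-recognition programs disagree: each
scores templates on its own scale (Z-scores, E-values, calibrated
probabilities), covers different regions of a target, and misses different
remote homologues.  `metathread` combines their outputs into something a
modeling pipeline can consume:

* **Template selection** — a Gaussian-kernel SVC over per-method score
  vectors (with explicit presence-mask features) estimates the probability
  that a candidate template is structurally related to the target,
  defined as TM-score ≥ 0.4 to the native fold.
* **Consensus alignments** — a Naive-Bayes classifier turns the component
  methods' alignments into a per-cell posterior matrix
  P(i ↔ j ∈ structure alignment), which scores a global Needleman–Wunsch
  dynamic program with free end gaps.
* **Contact prediction** — long-range contacts (heavy atoms ≤ 4.5 Å,
  |i−j| ≥ 5) predicted from template votes through the consensus
  alignments plus a knowledge-based pair potential
  U(a,b) = −ln[(N_obs+1)/(N_exp+1)], with an MCC-optimal reporting
  threshold (default 0.35).
* **Model ranking & confidence** — a pairwise-transform linear ranking SVM
  orders candidate models and a support-vector regressor estimates each
  model's TM-score to native, both from alignment-, geometry- and
  potential-derived features.
* **Structure metrics** — Kabsch superposition, TM-score, GDT, MaxSub,
  Gaussian-weighted RMSD, contact extraction, TM-score template
  clustering, ROC/MCC utilities.
* **Synthetic benchmarks** — compact toy proteins, decoys and templates at
  known TM-score, and mock threading methods with tunable score fidelity
  and alignment noise, giving exact ground truth for every stage.

It is aimed at structural bioinformaticians who want to train, dissect or
benchmark meta-threading machinery without installing ten third-party
threading programs; real method outputs can be fed in through a simple
tab-separated exchange format.

## Worked example

Generate a labelled synthetic benchmark, run the full pipeline, and
evaluate it against the ground truth:

```bash
metathread simulate --n-targets 12 --n-methods 4 --seed 7 --out demo/bench
metathread run --input demo/bench --seed 7 --out demo/run
metathread evaluate --run demo/run --truth demo/bench
```

The last command prints (numbers from this exact invocation):

```json
{
 "alignment_mcc_mean": 0.9680300786545881,
 "confidence_cc": 0.7596332221207938,
 "contact_fpr": 0.01782937125083315,
 "contact_mcc": 0.41581302181499585,
 "contact_tpr": 0.5098314606741573,
 "rank1_rate": 0.9166666666666666,
 "selection_auc": 0.852389594676346
}
```

Reading these: cross-validated template selection separates related from
unrelated templates with AUC 0.85 on this small benchmark; consensus
alignments agree with the generative reference maps at a mean MCC of 0.97
(each mock method alone sits near 0.82); at the shipped 0.35 threshold the
contact stage recovers 51% of native long-range contacts at a 1.8% false
positive rate; the ranker puts the best decoy at rank 1 for 92% of
targets; and the estimated TM-scores correlate with the true ones at
Pearson r = 0.76.  Larger benchmarks (the acceptance script below) give
tighter numbers.

Every run directory contains plain-TSV stage reports (`selection.tsv`,
`alignments.tsv`, `contacts.tsv`, `ranks.tsv`) and a `manifest.json` with
the full configuration and seed; re-running with the same seed reproduces
all reports byte for byte.

The same machinery is available as a library:

```python
from metathread.synthetic import build_benchmark
from metathread.evaluate import evaluate_template_selection

bench = build_benchmark(n_targets=30, n_methods=5, seed=1)
sel = evaluate_template_selection(bench, seed=1)
print(sel.auc_meta, sel.best_single_auc)
```

## Layout

```
src/metathread/
  io_model.py    domain types; FASTA/PDB readers; exchange TSV formats
  metrics.py     Kabsch, TM-score, GDT/MaxSub/wRMSD, contacts, ROC/MCC
  select.py      score normalization, sequence identity, template SVC
  consensus.py   Naive-Bayes posterior matrix + Needleman-Wunsch DP
  contacts.py    pair potential, contact features, SVC, tolerant matching
  ranking.py     ranking features, burial/secstr scores, SVM-rank, SVR
  synthetic.py   toy structures, decoys/templates, mock threaders
  evaluate.py    cross-validated stage evaluators
  pipeline.py    run orchestration + run evaluation
  cli.py         the `metathread` command
docs/methods.md  model assumptions, parameters, design choices, limits
```
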