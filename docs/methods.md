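# Methods

`metathread` implements the meta-threading layer of template-based protein
structure modeling: given the outputs of several independent
threading/fold-recognition methods for a target sequence, it (i) decides
which candidate templates are structurally related to the target,
(ii) builds one consensus target-to-template alignment per selected
template, (iii) predicts long-range inter-residue contacts from those
alignments, and (iv) ranks candidate structure models and estimates their
TM-score to the (unknown) native structure.  A synthetic benchmark
generator supplies labelled data for every stage so the whole pipeline is
trainable and testable offline.

## Structure metrics

All stages lean on a small structure-comparison core.

* **Kabsch superposition.**  Least-squares rigid superposition via SVD with
  the reflection corrected to a proper rotation.  Degenerate (collinear)
  point sets are rejected explicitly because the rotation about the line is
  then unconstrained.
* **TM-score.**  For aligned CA pairs, `TM = max over superpositions of
  (1/L_norm) * sum 1/(1 + (d_i/d0)^2)` with `d0 = 1.24 (L-15)^(1/3) - 1.8`,
  normalised by the native length.  For chains shorter than 21 residues the
  formula turns negative, so `d0` is clamped to 0.5 Å.  The maximisation
  seeds superpositions from contiguous alignment windows of lengths
  {L, L/2, L/4, 4} and refines each seed by iteratively re-superposing on
  the residues within a distance cutoff until the included set stabilises
  (the cutoff is relaxed in 0.5 Å steps whenever fewer than four residues
  qualify).  Seed starts are strided (about L/20) by default; the test
  suite checks agreement with an exhaustive stride-1 oracle to 0.01.
  A score of 0.4 or more is treated as fold-level structural similarity
  throughout (relatedness labels, clustering threshold, significance flag).
  Whether a domain-library hit should be normalised by domain or full-chain
  length is exposed as the `norm_length` argument; the default is the
  native (second) structure's length.
* **GDT / MaxSub / wRMSD.**  GDT is the mean over the 1/2/4/8 Å cutoffs of
  the maximal fraction of residues fitting under each cutoff, each cutoff
  maximised independently with the same seed-and-refine search.  MaxSub
  maximises the TM-like score of the subset within 3.5 Å.  wRMSD iterates
  Gaussian-reweighted superpositions with weight width 2.0 Å, 10 iterations
  or ΔwRMSD < 1e-4; the width is a free parameter in the literature and is
  fixed here for determinism.
* **Contacts.**  Two residues are in contact when any pair of their heavy
  atoms lies within 4.5 Å and at least four residues separate them in
  sequence (|i−j| ≥ 5).  Extraction uses a KD-tree over all heavy atoms.
* **Template clustering.**  Greedy centroid clustering on the pairwise
  TM-score matrix at threshold 0.4: repeatedly take the member with most
  remaining neighbours at or above threshold (ties: lexicographically
  smallest id) and remove it with its neighbours.  Deterministic,
  exhaustive and disjoint by construction.

## Template selection

Each threading method reports a raw score on its own scale.  Scores are
mapped to a common higher-is-better axis (Z-scores and probabilities kept,
E-values via −log10 with a 1e-180 floor) and standardized per method over
the target's candidate list; a zero-variance column standardizes to zero.
A method that fails to report a template is itself a signal in the
fold-recognition regime, so the feature vector carries an explicit
presence-mask bit per method (doubling the dimensionality) and missing
scores enter as 0 after standardization.

The classifier is a Gaussian-kernel SVC with probability calibration
(Platt-style sigmoid on held-out decision values), labels being "template
TM-score to native ≥ 0.4".  Hyperparameters (C ∈ {0.1, 1, 10},
γ ∈ {0.01, 0.1, 1}) are grid-searched inside the training folds only.
Evaluation is 2-fold cross-validation: each candidate's probability comes
from the fold model that never saw it.  Templates with more than 40%
sequence identity to the target (global BLOSUM62 alignment, gap open 11 /
extend 1, identities divided by the shorter length) are excluded from
training, evaluation and all downstream stages — they are trivial
homologues that would inflate every metric.

## Consensus alignments

For one target/template pair, every cell (i, j) of the target × template
grid receives a Naive-Bayes posterior probability of belonging to the true
structure alignment.  Two features per roster method: a Bernoulli
indicator (did the method align i to j?) and the method's hit confidence
discretized into 5 equal-width bins.  Conditional tables use add-one
smoothing; the class prior comes from training frequencies.  Because the
negative cell population is quadratic and redundant, training subsamples
negatives at 10:1 per reference pair.  Posteriors are per-cell and
independent; no row normalisation is applied.

The "hit confidence" fed to the aligner is the within-target rank quantile
of the method's normalized score (1 for the method's best template,
approaching 0 for its worst, 0 when absent).  This keeps the confidence in
[0, 1], monotone in the method's own ranking, and avoids circular
dependence on the meta-classifier.  An ablation flag (`use_confidence`)
drops the confidence feature entirely.

The posterior matrix is then the scoring function of a global
Needleman–Wunsch dynamic program with a linear gap penalty (default 0.1
per gapped cell — posteriors live in [0, 1], and 0.1 balances coverage
against precision on the synthetic fixtures) and free end gaps.  Traceback
ties resolve diagonal > up > left, which fixes the alignment uniquely.
The DP is checked exactly against brute-force enumeration of all monotone
alignments on small matrices.

## Contact prediction

Candidate pairs are all (i, j) with j − i ≥ 5.  Four features per pair:

1. the fraction of selected templates whose equivalent residues (through
   the consensus alignments) are in contact;
2. the mean selection probability of those voting templates;
3. the mean consensus-alignment confidence at the two mapped positions,
   averaged over voting templates;
4. a knowledge-based pair potential
   `U(a,b) = −ln[(N_obs(a,b)+1)/(N_exp(a,b)+1)]`, with expected counts from
   the endpoint residue-type marginals under contact-count conservation,
   derived from the training-fold native structures.

Means run over voting templates only; a pair no template covers gets an
all-zero sentinel for features 1–3 and can still be predicted from the
potential alone.  The classifier is a calibrated Gaussian-kernel SVC;
negatives are subsampled at 5:1 and the training set capped at 4000 rows
because contact classes are extremely unbalanced.  The reporting threshold
is chosen to maximise MCC on cross-validated probabilities (ties: lowest
threshold); the shipped default is 0.35.  Tolerant evaluation (±1/2/3
residues) uses greedy nearest-first matching with each native contact
consumable once — deterministic, and within the documented 1/2-approximation
bound of optimal bipartite matching in the tests.

## Model ranking and confidence

Per-model features: mean consensus-alignment confidence (Alignment), mean
alignment coverage (Coverage), agreement of the model's geometric 3-state
secondary structure with a provided prediction (PSIPRED-style match),
burial and secondary-structure preference log-odds scores, and — depending
on provenance — the template-cluster fraction (cluster-based sets) or the
mean TM-score of the model to its templates (trajectory-based sets).
External statistical-potential columns (DOPE, dFire, GA341, clustering
coefficients) are accepted as optional extra columns and excluded from the
model when absent rather than imputed.

The burial and secondary-structure scores are this package's own
formulations — there is no single canonical definition of these composite
quality terms:
burial state is the CA neighbour count within 10 Å in three bins
(<8, 8–13, ≥14), secondary structure is assigned geometrically from CA
i→i+2 / i→i+3 distances (helix: d(i,i+3) < 6 Å; strand: d(i,i+2) > 6.2 Å
and d(i,i+3) > 8.5 Å; else coil), and each score is the mean log-odds of
residue type given state against library-derived propensities with add-one
smoothing.  Both are isolated behind one interface so faithful versions
can replace them; the tests require only that they prefer natives over
heavily perturbed decoys in ≥80% of cases.

Ranking uses the pairwise transform: same-target model pairs whose true
TM-scores differ by more than 0.01 (near-ties are label noise) become
anti-symmetric feature-difference examples for a linear SVM; the learned
weight vector scores and orders models, ties broken by estimated TM then
model id.  Confidence is a Gaussian-kernel SVR of TM-score on the feature
vector (C ∈ {1, 10}, γ ∈ {0.003, 0.01, 0.1} grid-searched in the training
folds; ε = 0.02), predictions clipped to [0, 1].  Both models use grouped
2-fold cross-validation over targets.

## Synthetic benchmark

The generator emulates the data a meta-threading pipeline consumes,
with exact ground truth at every stage:

* **Toy proteins.**  Self-avoiding CA traces built segment-wise from
  helix/strand/coil virtual geometry (bond 3.8 ± 0.05 Å; helix
  θ=91°, τ=49.5°; strand θ=123°, τ=195°), confined to a sphere of radius
  3.5·N^(1/3) Å around the running centroid so chains pack at globule-like
  density (radius of gyration ≈ 11 Å at 80 residues) and form tertiary
  contacts.  One pseudo side-chain heavy atom sits 1.5 Å from each CA
  along the local bisector, enough geometry for the 4.5 Å contact rule.
  Sequences are sampled with composition bias by secondary-structure state
  and burial, which gives the burial/secondary-structure scores a real
  signal.
* **Decoys and templates.**  Decoys apply segment-wise rigid jitter plus
  per-atom Gaussian noise of a given magnitude; the true TM-score to the
  native is returned with each decoy.  Templates additionally delete short
  segments (≤15% of residues), renumber, and mutate the sequence to ~25%
  identity; the generative residue map is the reference alignment.
  Template perturbation magnitudes are drawn uniformly from 1.2–12 Å,
  which yields template pools spanning TM ≈ 0.2–0.9 with 30–50% positives
  at the 0.4 threshold.
* **Mock threading methods.**  A method with fidelity ρ scores a template
  by a monotone map of ρ·TM + (1−ρ)·noise onto its declared scale
  (Z-score: affine; E-value: 10^(−12·signal); probability: logistic).  Its
  alignment is the reference map with a fraction `align_noise` (default
  0.2) of pairs shifted by 1–3 template positions or deleted, repaired to
  monotonicity.  Hits are omitted entirely with probability
  0.9·σ(5·(0.4 − TM)) — the logistic detection-failure model that makes
  the presence mask informative.  Default rosters spread ρ over 0.5–0.85
  and cycle the three score types.
* **Ranking benchmark.**  Feature-level decoy sets: latent quality
  q ~ U(0.2, 0.9) per model, each feature q plus feature-specific Gaussian
  noise (σ between 0.07 and 0.20; bounded features clipped), true TM-score
  q plus observation noise σ = 0.08.

All randomness flows from one seeded generator in a fixed construction
order, so benchmarks, pipeline runs and reports are byte-reproducible
under a fixed seed.

What the generator does *not* emulate: real side-chain packing, realistic
sequence–structure compatibility beyond composition bias, correlated
errors between threading methods, and the long-tailed difficulty
distribution of real fold-recognition targets.  Passing the meta-gain
properties therefore shows the machinery extracts and combines the signal
it is given, not that the shipped models transfer to real threading
outputs — retraining on real data is expected.

## Problem sizes and numerical choices

The test suite exercises the meta-gain properties on ten replicate
benchmarks of 50 targets × 5 methods; the acceptance script uses three
replicates of 30 targets plus ten ranking replicates of 60 targets × 8
models.  These sizes keep full runs at desk scale while leaving the
qualitative orderings (meta beats best single method; consensus beats the
single-method average; classifier beats majority vote; combined ranker
beats every single feature) comfortably outside sampling noise.

Degenerate inputs are handled explicitly: single-class folds raise with a
re-split hint; zero-variance score columns standardize to zero; MCC is 0
by convention at any zero marginal; empty candidate lists yield empty
results; an empty posterior matrix, too few aligned pairs (<5 for
TM-score, <3 points for superposition) and non-symmetric TM matrices
raise.

## Known limitations

* The ten real threading programs are not wrapped; the exchange TSV is the
  integration surface and mock methods stand in for them.
* Structure assembly (Modeller/TASSER-style), side-chain rebuilding and
  force-field refinement are out of scope; the pipeline produces and
  consumes that stage's inputs/outputs (template clusters, alignments,
  contacts, per-model features) only.
* Burial/SecStr are substitute definitions, and sequence-based secondary
  structure prediction is approximated by the geometric assignment of the
  native when no external prediction is supplied.
* fr-TM-align-style sequence-independent structural alignment is not
  re-implemented; reference alignments at desk scale come from the
  generator's ground truth.
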