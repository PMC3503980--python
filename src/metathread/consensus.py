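"""Consensus target-to-template alignments.

A Naive-Bayes classifier estimates, for every (target residue, template
residue) cell, the posterior probability that the pair belongs to the true
structure alignment, from two features per roster method: whether the
method aligned the pair (Bernoulli indicator) and the method's hit
confidence (discretized into five equal-width bins).  The resulting
posterior matrix is then used as the scoring function of a global
Needleman-Wunsch dynamic program with a linear gap penalty and free end
gaps, yielding one consensus alignment per selected template.

Posteriors are computed per cell independently; no row normalisation is
applied.  All conditional tables use add-one smoothing so unseen feature
values never force a 0/1 posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from metathread.io_model import PairAlignment, ThreadingHit

#: Number of equal-width bins for the method-confidence feature.
N_CONFIDENCE_BINS = 5

#: Default linear gap penalty per gapped cell (posteriors live in [0, 1]).
DEFAULT_GAP_PENALTY = 0.1

#: Default negative:positive subsampling ratio for training cells.
NEGATIVE_SUBSAMPLE_RATIO = 10


def confidence_bin(confidence: float, n_bins: int = N_CONFIDENCE_BINS) -> int:
    """Equal-width bin index of a confidence in [0, 1]."""
    if not 0.0 <= confidence <= 1.0:
        raise ValueError("confidence must lie in [0, 1]")
    return min(int(confidence * n_bins), n_bins - 1)


@dataclass
class PairEvidence:
    """Per-method evidence for one residue-pair cell."""

    indicators: np.ndarray  # {0,1} per roster method
    confidences: np.ndarray  # hit confidence per method, 0 if method absent

    def bins(self, n_bins: int = N_CONFIDENCE_BINS) -> np.ndarray:
        return np.array([confidence_bin(c, n_bins) for c in self.confidences])


def collect_evidence(
    hits: Iterable[ThreadingHit],
    i: int,
    j: int,
    roster: Sequence[str],
    confidences: Mapping[str, float] | None = None,
) -> PairEvidence:
    """Evidence vector for target position ``i`` vs template position ``j``.

    ``hits`` are one target/template pair's hits; duplicate hits from one
    method are counted once.  ``confidences`` maps method name to its hit
    confidence (0 when absent).
    """
    roster = list(roster)
    idx = {m: k for k, m in enumerate(roster)}
    ind = np.zeros(len(roster))
    conf = np.zeros(len(roster))
    seen: set[str] = set()
    for hit in hits:
        if hit.method in seen:
            continue
        seen.add(hit.method)
        k = idx[hit.method]
        if (i, j) in set(hit.alignment):
            ind[k] = 1.0
        if confidences is not None:
            conf[k] = confidences.get(hit.method, 0.0)
    return PairEvidence(indicators=ind, confidences=conf)


@dataclass
class PosteriorMatrix:
    """Per-cell Bayesian probability of structural alignment membership."""

    matrix: np.ndarray  # target_len x template_len in [0, 1]
    prior: float  # class prior P(aligned) of the trained model

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0) or np.any(self.matrix > 1):
            raise ValueError("posterior entries must lie in [0, 1]")
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie in (0, 1)")


@dataclass
class NaiveBayesAligner:
    """Naive-Bayes model over per-method (indicator, confidence-bin) features.

    ``log_lik_ind[m, c, v]`` is log P(indicator_m = v | class c);
    ``log_lik_bin[m, c, b]`` is log P(bin_m = b | class c).  The
    ``use_confidence`` flag ablates the confidence feature.
    """

    roster: list[str]
    n_bins: int = N_CONFIDENCE_BINS
    use_confidence: bool = True
    log_prior: np.ndarray = field(default=None, repr=False)  # log P(class), shape (2,)
    log_lik_ind: np.ndarray = field(default=None, repr=False)  # (m, 2, 2)
    log_lik_bin: np.ndarray = field(default=None, repr=False)  # (m, 2, n_bins)

    @property
    def prior(self) -> float:
        return float(np.exp(self.log_prior[1]))

    def fit(
        self,
        indicators: np.ndarray,
        confidence_bins: np.ndarray,
        labels: Sequence[bool],
    ) -> "NaiveBayesAligner":
        """Estimate conditional tables with add-one smoothing.

        ``indicators``: (n_samples, n_methods) in {0,1};
        ``confidence_bins``: (n_samples, n_methods) in [0, n_bins).
        """
        ind = np.asarray(indicators, dtype=int)
        bins = np.asarray(confidence_bins, dtype=int)
        y = np.asarray(labels, dtype=int)
        if ind.shape != bins.shape or len(ind) != len(y):
            raise ValueError("feature arrays and labels must align")
        if y.min() == y.max():
            raise ValueError("both classes must be present")
        m = len(self.roster)
        counts = np.array([(y == 0).sum(), (y == 1).sum()], dtype=float)
        self.log_prior = np.log(counts / counts.sum())
        self.log_lik_ind = np.zeros((m, 2, 2))
        self.log_lik_bin = np.zeros((m, 2, self.n_bins))
        for c in (0, 1):
            sub_ind = ind[y == c]
            sub_bin = bins[y == c]
            for k in range(m):
                ind_counts = np.bincount(sub_ind[:, k], minlength=2).astype(float) + 1.0
                self.log_lik_ind[k, c] = np.log(ind_counts / ind_counts.sum())
                bin_counts = (
                    np.bincount(sub_bin[:, k], minlength=self.n_bins).astype(float) + 1.0
                )
                self.log_lik_bin[k, c] = np.log(bin_counts / bin_counts.sum())
        return self

    def log_odds(self, indicators: np.ndarray, confidence_bins: np.ndarray) -> np.ndarray:
        """Posterior log-odds for rows of (indicator, bin) feature vectors."""
        ind = np.asarray(indicators, dtype=int)
        bins = np.asarray(confidence_bins, dtype=int)
        lo = np.full(len(ind), self.log_prior[1] - self.log_prior[0])
        for k in range(len(self.roster)):
            lo += self.log_lik_ind[k, 1, ind[:, k]] - self.log_lik_ind[k, 0, ind[:, k]]
            if self.use_confidence:
                lo += (
                    self.log_lik_bin[k, 1, bins[:, k]] - self.log_lik_bin[k, 0, bins[:, k]]
                )
        return lo

    def posterior(self, indicators: np.ndarray, confidence_bins: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.log_odds(indicators, confidence_bins)))

    def background_posterior(self, confidence_bins: np.ndarray) -> float:
        """Posterior of a zero-evidence cell (all indicators 0) under the
        given per-method confidence bins — the matrix's baseline value."""
        ind = np.zeros((1, len(self.roster)), dtype=int)
        return float(self.posterior(ind, confidence_bins.reshape(1, -1))[0])


def train_alignment_nb(
    evidence_indicators: np.ndarray,
    evidence_bins: np.ndarray,
    labels: Sequence[bool],
    roster: Sequence[str],
    n_bins: int = N_CONFIDENCE_BINS,
    use_confidence: bool = True,
) -> NaiveBayesAligner:
    """Fit the consensus-alignment Naive-Bayes model; see
    :class:`NaiveBayesAligner` for the feature encoding."""
    nb = NaiveBayesAligner(roster=list(roster), n_bins=n_bins, use_confidence=use_confidence)
    return nb.fit(evidence_indicators, evidence_bins, labels)


def posterior_matrix(
    nb: NaiveBayesAligner,
    hits: Sequence[ThreadingHit],
    target_len: int,
    template_len: int,
    confidences: Mapping[str, float] | None = None,
) -> PosteriorMatrix:
    """Posterior matrix for one target/template pair.

    Adding an agreeing method with a positive likelihood ratio never
    decreases a cell's posterior (Naive-Bayes monotonicity).  Raises when a
    hit's aligned pairs fall outside the stated dimensions.
    """
    m = len(nb.roster)
    idx = {name: k for k, name in enumerate(nb.roster)}
    conf_bins = np.zeros(m, dtype=int)
    if confidences:
        for name, c in confidences.items():
            if name in idx:
                conf_bins[idx[name]] = confidence_bin(c, nb.n_bins)

    # log-odds of the zero-evidence cell, then per-method deltas where aligned
    base_ind = np.zeros((1, m), dtype=int)
    base = nb.log_odds(base_ind, conf_bins.reshape(1, -1))[0]
    lo = np.full((target_len, template_len), base)
    seen: set[str] = set()
    for hit in hits:
        if hit.method not in idx or hit.method in seen:
            continue
        seen.add(hit.method)
        k = idx[hit.method]
        delta = (nb.log_lik_ind[k, 1, 1] - nb.log_lik_ind[k, 0, 1]) - (
            nb.log_lik_ind[k, 1, 0] - nb.log_lik_ind[k, 0, 0]
        )
        for t, q in hit.alignment:
            if not (1 <= t <= target_len and 1 <= q <= template_len):
                raise ValueError(
                    f"aligned pair ({t},{q}) outside {target_len}x{template_len} matrix"
                )
            lo[t - 1, q - 1] += delta
    matrix = 1.0 / (1.0 + np.exp(-lo))
    return PosteriorMatrix(matrix=matrix, prior=nb.prior)


# ---------------------------------------------------------------------------
# Needleman-Wunsch over the posterior matrix
# ---------------------------------------------------------------------------


def needleman_wunsch_posterior(
    matrix: np.ndarray,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> tuple[list[tuple[int, int]], float]:
    """Global DP over a posterior matrix with linear gaps and free end gaps.

    Maximises sum of matched-cell posteriors minus ``gap_penalty`` per
    internal gapped cell.  Returns 1-based aligned pairs and the optimal
    score.  Traceback ties resolve diagonal > up > left; among equal-scoring
    end cells the first one along the last column (top to bottom) then the
    last row (left to right) is taken.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise ValueError("posterior matrix must be non-empty and 2-D")
    if not np.all(np.isfinite(m)):
        raise ValueError("posterior matrix must be finite")
    nt, nq = m.shape
    g = float(gap_penalty)
    score = np.zeros((nt + 1, nq + 1))
    ptr = np.zeros((nt + 1, nq + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    for i in range(1, nt + 1):
        row_s = score[i]
        prev_s = score[i - 1]
        for j in range(1, nq + 1):
            diag = prev_s[j - 1] + m[i - 1, j - 1]
            up = prev_s[j] - g
            left = row_s[j - 1] - g
            if diag >= up and diag >= left:
                row_s[j] = diag
                ptr[i, j] = 1
            elif up >= left:
                row_s[j] = up
                ptr[i, j] = 2
            else:
                row_s[j] = left
                ptr[i, j] = 3
    # free trailing gaps: best cell on the last column or last row
    best_val, best_cell = -np.inf, (nt, nq)
    for i in range(1, nt + 1):
        if score[i, nq] > best_val:
            best_val, best_cell = score[i, nq], (i, nq)
    for j in range(1, nq + 1):
        if score[nt, j] > best_val:
            best_val, best_cell = score[nt, j], (nt, j)
    if 0.0 > best_val:
        return [], 0.0
    pairs: list[tuple[int, int]] = []
    i, j = best_cell
    while i > 0 and j > 0:
        step = ptr[i, j]
        if step == 1:
            pairs.append((i, j))
            i, j = i - 1, j - 1
        elif step == 2:
            i -= 1
        elif step == 3:
            j -= 1
        else:
            break
        if score[i, j] == 0.0 and (i == 0 or j == 0):
            break
    pairs.reverse()
    return pairs, float(best_val)


def consensus_alignment(
    nb: NaiveBayesAligner,
    hits: Sequence[ThreadingHit],
    target_id: str,
    template_id: str,
    target_len: int,
    template_len: int,
    confidences: Mapping[str, float] | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> PairAlignment:
    """Consensus alignment for one target/template pair, with per-pair
    confidences taken from the posterior matrix along the DP path."""
    pm = posterior_matrix(nb, hits, target_len, template_len, confidences)
    pairs, _ = needleman_wunsch_posterior(pm.matrix, gap_penalty)
    confs = [float(pm.matrix[t - 1, q - 1]) for t, q in pairs]
    return PairAlignment(
        target_id=target_id,
        template_id=template_id,
        pairs=pairs,
        per_pair_confidence=confs,
        target_length=target_len,
        template_length=template_len,
    )


def consensus_for_target(
    nb: NaiveBayesAligner,
    hits: Sequence[ThreadingHit],
    target_id: str,
    target_len: int,
    template_lens: Mapping[str, int],
    selected_templates: Sequence[str],
    confidences: Mapping[str, Mapping[str, float]] | None = None,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> dict[str, PairAlignment]:
    """One consensus alignment per selected template.

    Templates without any hit are skipped with a warning; an empty
    selection yields an empty mapping.
    """
    import logging

    logger = logging.getLogger(__name__)
    by_template: dict[str, list[ThreadingHit]] = {}
    for hit in hits:
        by_template.setdefault(hit.template_id, []).append(hit)
    out: dict[str, PairAlignment] = {}
    for tid in selected_templates:
        tpl_hits = by_template.get(tid, [])
        if not tpl_hits:
            logger.warning("template %s has no hits; skipped", tid)
            continue
        conf = confidences.get(tid) if confidences else None
        out[tid] = consensus_alignment(
            nb,
            tpl_hits,
            target_id,
            tid,
            target_len,
            template_lens[tid],
            confidences=conf,
            gap_penalty=gap_penalty,
        )
    return out


def build_alignment_training(
    per_pair_data: Sequence[
        tuple[Sequence[ThreadingHit], Mapping[str, float], set[tuple[int, int]], int, int]
    ],
    roster: Sequence[str],
    negative_ratio: int = NEGATIVE_SUBSAMPLE_RATIO,
    rng: np.random.Generator | None = None,
    n_bins: int = N_CONFIDENCE_BINS,
):
    """Training arrays for the Naive-Bayes aligner.

    Each element of ``per_pair_data`` describes one target/template pair:
    (hits, per-method confidences, reference pair set, target_len,
    template_len).  All reference cells become positives; negatives are
    subsampled from the remaining cells at ``negative_ratio``:1 (the full
    negative set is quadratic and overwhelmingly redundant).
    """
    rng = rng or np.random.default_rng(0)
    roster = list(roster)
    idx = {m: k for k, m in enumerate(roster)}
    nm = len(roster)
    ind_rows, bin_rows, labels = [], [], []
    for hits, confs, ref_pairs, target_len, template_len in per_pair_data:
        conf_bins = np.zeros(nm, dtype=int)
        aligned_of_method: dict[int, set[tuple[int, int]]] = {}
        seen: set[str] = set()
        for hit in hits:
            if hit.method in seen or hit.method not in idx:
                continue
            seen.add(hit.method)
            k = idx[hit.method]
            aligned_of_method[k] = set(hit.alignment)
            conf_bins[k] = confidence_bin(confs.get(hit.method, 0.0), n_bins)

        def evidence_row(cell: tuple[int, int]) -> np.ndarray:
            row = np.zeros(nm, dtype=int)
            for k, pairs in aligned_of_method.items():
                if cell in pairs:
                    row[k] = 1
            return row

        positives = sorted(ref_pairs)
        n_neg = min(
            negative_ratio * len(positives), target_len * template_len - len(positives)
        )
        ref = set(ref_pairs)
        negatives: list[tuple[int, int]] = []
        while len(negatives) < n_neg:
            t = int(rng.integers(1, target_len + 1))
            q = int(rng.integers(1, template_len + 1))
            if (t, q) not in ref:
                negatives.append((t, q))
        for cell, lab in [(c, 1) for c in positives] + [(c, 0) for c in negatives]:
            ind_rows.append(evidence_row(cell))
            bin_rows.append(conf_bins)
            labels.append(lab)
    return np.array(ind_rows), np.array(bin_rows), np.array(labels, dtype=int)
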