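"""Structure-comparison primitives: superposition, TM-score, GDT, MaxSub,
wRMSD, contact extraction, TM-score clustering and classification metrics.

These quantities serve three roles throughout the toolkit: ground-truth
labels (template relatedness at TM-score >= 0.4), per-model features (mean
TM-score to templates) and evaluation metrics (ROC/AUC, MCC, rank curves).

TM-score, GDT and MaxSub all maximise a superposition-dependent quantity.
The search here seeds Kabsch superpositions from contiguous alignment
windows of several lengths and refines each seed by iterative inclusion of
well-fitting residues, which reproduces the behaviour of the published
heuristics at the problem sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from sklearn import metrics as _skm

from metathread.io_model import (
    CONTACT_DISTANCE_CUTOFF,
    CONTACT_MIN_SEPARATION,
    ContactRecord,
    PairAlignment,
    StructureCoords,
)

#: TM-score at or above this value indicates fold-level structural similarity.
TM_SIGNIFICANCE = 0.4

#: GDT distance cutoffs in Angstrom.
GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)

#: MaxSub inclusion cutoff in Angstrom.
MAXSUB_CUTOFF = 3.5

#: Gaussian width (Angstrom) of the wRMSD weights; fixed for determinism.
WRMSD_SIGMA = 2.0


@dataclass
class Superposition:
    """A rigid-body superposition: y ~ x @ rotation.T + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class SimilarityScores:
    """Bundle of model-vs-native similarity scores."""

    tm_score: float
    gdt: float
    maxsub: float
    wrmsd: float
    rmsd: float

    @property
    def significant(self) -> bool:
        return self.tm_score >= TM_SIGNIFICANCE


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def _kabsch(x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares rigid superposition of x onto y (no degeneracy checks).

    Returns (rotation, translation, rmsd or weighted rmsd).
    """
    if weights is None:
        w = np.ones(len(x))
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    x0 = x - xc
    y0 = y - yc
    h = (w[:, None] * x0).T @ y0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = yc - rot @ xc
    diff = x @ rot.T + trans - y
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / wsum))
    return rot, trans, rmsd


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Optimal rigid superposition of ``coords_a`` onto ``coords_b``.

    Both arrays must be (N, 3) with N >= 3 and non-degenerate (not all
    collinear), otherwise a ValueError is raised.  The returned rotation is
    always proper (determinant +1).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if len(a) < 3:
        raise ValueError("superposition requires at least 3 points")
    for arr, name in ((a, "first"), (b, "second")):
        centered = arr - arr.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise ValueError(f"{name} point set is degenerate (collinear)")
    rot, trans, rmsd = _kabsch(a, b)
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


# ---------------------------------------------------------------------------
# TM-score and friends
# ---------------------------------------------------------------------------


def tm_d0(length: int) -> float:
    """Length-dependent TM-score scale d0; clamped to 0.5 A for short chains."""
    if length < 21:
        return 0.5
    d0 = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    return max(d0, 0.5)


def _seed_windows(n: int, exhaustive: bool) -> list[tuple[int, int]]:
    lengths = sorted({n, max(n // 2, 4), max(n // 4, 4), 4}, reverse=True)
    windows = []
    for wlen in lengths:
        if wlen > n:
            continue
        stride = 1 if exhaustive else max(1, n // 20)
        starts = list(range(0, n - wlen + 1, stride))
        if starts[-1] != n - wlen:
            starts.append(n - wlen)
        windows.extend((s, wlen) for s in starts)
    return windows


def _iterative_superpose_score(
    xm: np.ndarray,
    xn: np.ndarray,
    score_of_d: "callable",
    d_start: float,
    exhaustive: bool = False,
    max_iter: int = 20,
):
    """Generic seed-and-refine superposition search.

    For every seed window, superpose on the window, then iteratively
    re-superpose on the residues within a distance cutoff until the included
    set stops changing; the cutoff is relaxed when fewer than 4 residues
    qualify.  Returns the best score over all visited superpositions.
    """
    n = len(xm)
    best = -np.inf
    for start, wlen in _seed_windows(n, exhaustive):
        idx = np.arange(start, start + wlen)
        prev_key = None
        cutoff = d_start
        for _ in range(max_iter):
            rot, trans, _ = _kabsch(xm[idx], xn[idx])
            d = np.sqrt((((xm @ rot.T + trans) - xn) ** 2).sum(axis=1))
            score = score_of_d(d)
            if score > best:
                best = score
            sel = np.flatnonzero(d < cutoff)
            while len(sel) < 4 and cutoff < 50.0:
                cutoff += 0.5
                sel = np.flatnonzero(d < cutoff)
            key = sel.tobytes()
            if key == prev_key or len(sel) < 3:
                break
            prev_key = key
            idx = sel
    return best


def tm_score_coords(
    model_xyz: np.ndarray,
    native_xyz: np.ndarray,
    norm_length: int,
    exhaustive: bool = False,
) -> float:
    """TM-score between aligned coordinate sets, normalised by ``norm_length``.

    ``model_xyz`` and ``native_xyz`` are (N, 3) arrays of equivalent CA
    positions (N aligned pairs); N >= 5 is required.
    """
    xm = np.asarray(model_xyz, dtype=float)
    xn = np.asarray(native_xyz, dtype=float)
    if len(xm) != len(xn) or len(xm) < 5:
        raise ValueError("TM-score requires >= 5 aligned pairs of equal count")
    d0 = tm_d0(norm_length)

    def score(d: np.ndarray) -> float:
        return float((1.0 / (1.0 + (d / d0) ** 2)).sum() / norm_length)

    return _iterative_superpose_score(xm, xn, score, d_start=max(d0, 1.0), exhaustive=exhaustive)


def _aligned_ca(
    model: StructureCoords, native: StructureCoords, pairs: Sequence[tuple[int, int]] | None
):
    """CA coordinate arrays for aligned (model, native) residue index pairs."""
    if pairs is None:
        if len(model) != len(native):
            raise ValueError("identity alignment requires equal lengths")
        return model.ca_array(), native.ca_array()
    m_idx = {r.index: k for k, r in enumerate(model.residues)}
    n_idx = {r.index: k for k, r in enumerate(native.residues)}
    mm, nn = [], []
    for mi, ni in pairs:
        if mi not in m_idx or ni not in n_idx:
            raise ValueError(f"aligned pair ({mi},{ni}) outside structures")
        mm.append(m_idx[mi])
        nn.append(n_idx[ni])
    return model.ca_array()[mm], native.ca_array()[nn]


def tm_score(
    model: StructureCoords,
    native: StructureCoords,
    pairs: Sequence[tuple[int, int]] | None = None,
    exhaustive: bool = False,
    norm_length: int | None = None,
) -> float:
    """TM-score of ``model`` against ``native`` over aligned residue pairs.

    ``pairs`` maps model residue indices to native residue indices
    (1-based); ``None`` means the identity alignment of two equal-length
    structures.  The score is normalised by the native length unless
    ``norm_length`` overrides it (e.g. to normalise domain-library hits by
    the full chain length).
    """
    xm, xn = _aligned_ca(model, native, pairs)
    return tm_score_coords(xm, xn, norm_length or len(native), exhaustive=exhaustive)


def gdt_maxsub_wrmsd(
    model: StructureCoords,
    native: StructureCoords,
    pairs: Sequence[tuple[int, int]] | None = None,
    exhaustive: bool = False,
) -> SimilarityScores:
    """Full similarity bundle: TM-score, GDT, MaxSub, wRMSD and CA-RMSD.

    GDT is the mean, over the 1/2/4/8 A cutoffs, of the maximal fraction of
    native residues fitting under each cutoff; MaxSub finds the largest
    subset fitting under 3.5 A and scores it TM-like; wRMSD iterates
    Gaussian-reweighted superpositions (width 2 A).
    """
    xm, xn = _aligned_ca(model, native, pairs)
    n_norm = len(native)
    if len(xm) < 5:
        raise ValueError("similarity scores require >= 5 aligned pairs")

    tm = tm_score_coords(xm, xn, n_norm, exhaustive=exhaustive)

    gdt_fracs = []
    for cutoff in GDT_CUTOFFS:

        def frac(d: np.ndarray, _c=cutoff) -> float:
            return float((d <= _c).sum() / n_norm)

        gdt_fracs.append(
            _iterative_superpose_score(xm, xn, frac, d_start=cutoff, exhaustive=exhaustive)
        )
    gdt = float(np.mean(gdt_fracs))

    def maxsub_score(d: np.ndarray) -> float:
        sel = d <= MAXSUB_CUTOFF
        return float((1.0 / (1.0 + (d[sel] / MAXSUB_CUTOFF) ** 2)).sum() / n_norm)

    maxsub = _iterative_superpose_score(
        xm, xn, maxsub_score, d_start=MAXSUB_CUTOFF, exhaustive=exhaustive
    )

    rmsd = _kabsch(xm, xn)[2]
    wrmsd = _weighted_rmsd(xm, xn)
    return SimilarityScores(tm_score=tm, gdt=gdt, maxsub=maxsub, wrmsd=wrmsd, rmsd=rmsd)


def _weighted_rmsd(xm: np.ndarray, xn: np.ndarray, n_iter: int = 10, tol: float = 1e-4) -> float:
    """Gaussian-weighted RMSD with iterative reweighting."""
    w = np.ones(len(xm))
    prev = np.inf
    wrmsd = 0.0
    for _ in range(n_iter):
        rot, trans, _ = _kabsch(xm, xn, weights=w)
        d2 = (((xm @ rot.T + trans) - xn) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2.0 * WRMSD_SIGMA**2))
        wsum = w.sum()
        if wsum <= 0:
            break
        wrmsd = float(np.sqrt((w * d2).sum() / wsum))
        if abs(prev - wrmsd) < tol:
            break
        prev = wrmsd
    return wrmsd


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def extract_contacts(
    structure: StructureCoords,
    cutoff: float = CONTACT_DISTANCE_CUTOFF,
    min_separation: int = CONTACT_MIN_SEPARATION,
) -> set[ContactRecord]:
    """Long-range contacts of a structure.

    A contact is an unordered residue pair whose closest heavy atoms lie
    within ``cutoff`` (4.5 A) and which are separated in sequence by at
    least ``min_separation`` (i.e. at least 4 intervening residues).
    Residue numbering follows the structure's residue indices.
    """
    coords = []
    res_of_atom = []
    for res in structure.residues:
        for _, x, y, z in res.atoms:
            coords.append((x, y, z))
            res_of_atom.append(res.index)
    if not coords:
        return set()
    coords = np.asarray(coords)
    res_of_atom = np.asarray(res_of_atom)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    out: set[ContactRecord] = set()
    for a, b in pairs:
        i, j = int(res_of_atom[a]), int(res_of_atom[b])
        if abs(i - j) >= min_separation:
            out.add(ContactRecord(i=min(i, j), j=max(i, j), label=True))
    return out


# ---------------------------------------------------------------------------
# TM-score clustering (template pre-clustering)
# ---------------------------------------------------------------------------


def cluster_by_tmscore(
    pairwise_tm: np.ndarray,
    ids: Sequence[str] | None = None,
    threshold: float = TM_SIGNIFICANCE,
) -> list[list[str]]:
    """Greedy centroid clustering of templates at a TM-score threshold.

    Repeatedly picks the member with the most remaining neighbours at
    TM >= threshold (ties broken by lowest id), forms a cluster from it and
    its neighbours, removes them and repeats.  The returned partition is
    exhaustive and disjoint; each cluster lists the centroid first.
    """
    m = np.asarray(pairwise_tm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pairwise TM matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("pairwise TM matrix must be symmetric")
    n = m.shape[0]
    if ids is None:
        ids = [f"T{i:04d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("ids length must match matrix size")
    order = sorted(range(n), key=lambda k: ids[k])
    remaining = set(range(n))
    clusters: list[list[str]] = []
    while remaining:
        best_k, best_count = None, -1
        for k in order:
            if k not in remaining:
                continue
            count = sum(
                1 for j in remaining if j != k and m[k, j] >= threshold
            )
            if count > best_count:
                best_k, best_count = k, count
        members = [best_k] + sorted(
            (j for j in remaining if j != best_k and m[best_k, j] >= threshold),
            key=lambda j: ids[j],
        )
        clusters.append([ids[j] for j in members])
        remaining -= set(members)
    return clusters


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


def confusion_stats(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(TPR, FPR, MCC, precision) from confusion counts.

    By convention each rate is 0 when its denominator is 0, and MCC is 0
    whenever any marginal is zero.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    tpr = tp / (tp + fn) if tp + fn else 0.0
    fpr = fp / (fp + tn) if fp + tn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return float(tpr), float(fpr), float(mcc), float(precision)


def mcc_from_counts(tp: int, fp: int, tn: int, fn: int) -> float:
    return confusion_stats(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))[2]


def alignment_mcc(predicted: PairAlignment, reference: PairAlignment) -> float:
    """Matthews correlation of a predicted alignment against a reference.

    The classification universe is the full target x template residue-pair
    grid; positives are the reference's aligned pairs.
    """
    if (predicted.target_id, predicted.template_id) != (
        reference.target_id,
        reference.template_id,
    ):
        raise ValueError("alignments compare different target/template pairs")
    total = reference.target_length * reference.template_length
    if total == 0:
        raise ValueError("reference alignment lacks grid dimensions")
    pred = set(predicted.pairs)
    ref = set(reference.pairs)
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = total - tp - fp - fn
    return mcc_from_counts(tp, fp, tn, fn)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]):
    """ROC curve and trapezoidal AUC via a threshold sweep with tied scores
    grouped.  Raises on single-class input."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    auc = float(_skm.auc(fpr, tpr))
    return fpr, tpr, auc


def tpr_at_fpr(scores: Sequence[float], labels: Sequence[bool], fpr_target: float) -> float:
    """TPR of the ROC curve linearly interpolated at a fixed FPR."""
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(np.interp(fpr_target, fpr, tpr))
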