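"""Synthetic threading benchmark generator.

Everything the pipeline needs is generated offline with ground truth for
every stage: toy protein structures (self-avoiding CA traces with a pseudo
side-chain atom per residue), controlled decoys and templates at known
TM-score to the native, and mock threading methods with heterogeneous score
scales whose scores correlate with true target-template TM-score and whose
alignments carry controllable error rates.

All randomness flows from a single :class:`numpy.random.Generator` seeded
once per benchmark; the draw order is fixed by the construction order of
targets, templates, decoys and hits, which makes every artefact
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from metathread.io_model import (
    ContactRecord,
    StructureCoords,
    Residue,
    TargetSequence,
    ThreadingHit,
    write_fasta,
    write_structure,
    write_threading_hits,
    read_fasta,
    read_structure,
    read_threading_hits,
)
from metathread.metrics import extract_contacts, tm_score_coords

# --- CA-trace virtual geometry (bond length fixed, angles by SS state) -----

CA_BOND = 3.8
CA_BOND_JITTER = 0.05  # keeps consecutive CA-CA within [3.75, 3.85]
MIN_NONLOCAL_CA_DIST = 3.5  # self-avoidance radius

# Virtual (bond angle, torsion) in degrees for ideal secondary structure.
HELIX_GEOMETRY = (91.0, 49.5)
STRAND_GEOMETRY = (123.0, 195.0)

#: Pseudo side-chain heavy atom distance from CA, Angstrom.
SIDECHAIN_BOND = 1.5

# Residue pools used for composition bias.  Sequences are sampled from a
# mixture of the secondary-structure pool, the burial pool and the uniform
# background, which gives burial and secondary-structure log-odds scores a
# real signal to pick up.
SS_POOLS = {
    "H": "ALEQMKRH",
    "E": "VIFYWTC",
    "C": "GPSND",
}
BURIAL_POOLS = {
    "buried": "AVLIFMWC",
    "exposed": "EKRQNDSTHPG",
}
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MethodSpec:
    """Configuration of one mock threading method."""

    name: str
    score_type: str
    rho: float  # score fidelity: correlation of the latent signal with TM
    align_noise: float  # fraction of aligned pairs corrupted

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.align_noise <= 1.0:
            raise ValueError("align_noise must lie in [0, 1]")


@dataclass
class BenchmarkTemplate:
    id: str
    structure: StructureCoords
    true_tm: float
    reference_pairs: list[tuple[int, int]]  # target pos -> template pos


@dataclass
class BenchmarkDecoy:
    id: str
    structure: StructureCoords
    true_tm: float


@dataclass
class BenchmarkTarget:
    sequence: TargetSequence
    native: StructureCoords
    contacts: set[ContactRecord]
    templates: dict[str, BenchmarkTemplate]
    decoys: list[BenchmarkDecoy]


@dataclass
class BenchmarkConfig:
    """Generation parameters; defaults define the standard study conditions."""

    n_templates: int = 8
    n_decoys: int = 6
    length_range: tuple[int, int] = (60, 100)
    template_magnitude_range: tuple[float, float] = (1.2, 12.0)
    decoy_magnitude_range: tuple[float, float] = (0.3, 6.0)
    template_identity: float = 0.25  # fraction of target residues kept verbatim
    max_deletion_fraction: float = 0.15
    alignment_noise: float = 0.2
    score_types: tuple[str, ...] = ("zscore", "evalue", "probability")
    rho_range: tuple[float, float] = (0.5, 0.85)


@dataclass
class SyntheticBenchmark:
    targets: dict[str, BenchmarkTarget]
    hits: dict[str, list[ThreadingHit]]
    methods: list[MethodSpec]
    seed: int
    config: BenchmarkConfig = field(default_factory=BenchmarkConfig)

    def target_ids(self) -> list[str]:
        return sorted(self.targets)


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _place_next(a, b, c, r, theta_deg, tau_deg):
    """NeRF placement of the next CA from the last three positions."""
    theta = math.radians(theta_deg)
    tau = math.radians(tau_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.column_stack([bc, np.cross(n, bc), n])
    d = np.array(
        [-r * math.cos(theta), r * math.sin(theta) * math.cos(tau), r * math.sin(theta) * math.sin(tau)]
    )
    return c + m @ d


def _sample_segments(n_res: int, rng: np.random.Generator) -> list[str]:
    """Per-residue secondary-structure labels from random H/E/C segments."""
    labels: list[str] = []
    while len(labels) < n_res:
        kind = rng.choice(["H", "E", "C"], p=[0.4, 0.3, 0.3])
        if kind == "H":
            length = int(rng.integers(6, 16))
        elif kind == "E":
            length = int(rng.integers(4, 9))
        else:
            length = int(rng.integers(2, 7))
        labels.extend([kind] * length)
    return labels[:n_res]


def _segment_geometry(kind: str, rng: np.random.Generator) -> tuple[float, float]:
    if kind == "H":
        theta, tau = HELIX_GEOMETRY
        return theta + rng.normal(0, 2.0), tau + rng.normal(0, 3.0)
    if kind == "E":
        theta, tau = STRAND_GEOMETRY
        return theta + rng.normal(0, 3.0), tau + rng.normal(0, 5.0)
    return float(rng.uniform(85, 140)), float(rng.uniform(-180, 180))


#: Confinement radius scale: the growing chain is kept within
#: ``CONFINEMENT_SCALE * n_res**(1/3)`` Angstrom of its centroid, which gives
#: globule-like compactness (radius of gyration close to folded proteins).
CONFINEMENT_SCALE = 3.5


def _build_trace(n_res: int, ss: list[str], rng: np.random.Generator) -> np.ndarray | None:
    """Self-avoiding CA trace following the segment geometry, confined to a
    sphere so the chain folds back on itself and forms tertiary contacts."""
    radius = CONFINEMENT_SCALE * n_res ** (1.0 / 3.0)
    xyz = np.zeros((n_res, 3))
    r0 = CA_BOND + rng.uniform(-CA_BOND_JITTER, CA_BOND_JITTER)
    xyz[1] = (r0, 0.0, 0.0)
    theta0, _ = _segment_geometry(ss[1], rng)
    ang = math.radians(180.0 - theta0)
    r1 = CA_BOND + rng.uniform(-CA_BOND_JITTER, CA_BOND_JITTER)
    xyz[2] = xyz[1] + (r1 * math.cos(ang), r1 * math.sin(ang), 0.0)
    for i in range(3, n_res):
        r = CA_BOND + rng.uniform(-CA_BOND_JITTER, CA_BOND_JITTER)
        centroid = xyz[:i].mean(axis=0)

        def ok(c: np.ndarray) -> bool:
            if np.min(np.linalg.norm(xyz[: i - 1] - c, axis=1)) < MIN_NONLOCAL_CA_DIST:
                return False
            return np.linalg.norm(c - centroid) <= radius

        placed = False
        for attempt in range(60):
            if attempt == 0 and ss[i] != "C":
                theta, tau = _segment_geometry(ss[i], rng)
                cand = _place_next(xyz[i - 3], xyz[i - 2], xyz[i - 1], r, theta, tau)
                if ok(cand):
                    xyz[i] = cand
                    placed = True
                    break
                continue
            # coil geometry (also the relaxation path when regular geometry
            # clashes or leaves the confinement sphere): pick the most
            # compact of a few admissible candidates
            best = None
            for _ in range(6):
                theta = float(rng.uniform(85, 140))
                tau = float(rng.uniform(-180, 180))
                c = _place_next(xyz[i - 3], xyz[i - 2], xyz[i - 1], r, theta, tau)
                if not ok(c):
                    continue
                dist = np.linalg.norm(c - centroid)
                if best is None or dist < best[0]:
                    best = (dist, c)
            if best is not None:
                xyz[i] = best[1]
                placed = True
                break
        if not placed:
            return None
    return xyz


def _sidechain_positions(xyz: np.ndarray) -> np.ndarray:
    """One pseudo heavy atom per residue, 1.5 A from CA along the local
    bisector pointing away from the chain (deterministic)."""
    n = len(xyz)
    cb = np.zeros_like(xyz)
    for i in range(n):
        lo = xyz[i - 1] if i > 0 else xyz[i + 1]
        hi = xyz[i + 1] if i < n - 1 else xyz[i - 1]
        v = 2.0 * xyz[i] - lo - hi
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            v = np.array([0.0, 0.0, 1.0])
            norm = 1.0
        cb[i] = xyz[i] + SIDECHAIN_BOND * v / norm
    return cb


def _burial_labels(xyz: np.ndarray) -> list[str]:
    from scipy.spatial import cKDTree

    tree = cKDTree(xyz)
    counts = np.array([len(tree.query_ball_point(p, 10.0)) - 1 for p in xyz])
    median = np.median(counts)
    return ["buried" if c > median else "exposed" for c in counts]


def _sample_sequence(ss: list[str], burial: list[str], rng: np.random.Generator) -> str:
    seq = []
    for s, b in zip(ss, burial):
        u = rng.uniform()
        if u < 0.45:
            pool = SS_POOLS[s]
        elif u < 0.8:
            pool = BURIAL_POOLS[b]
        else:
            pool = ALL_AA
        seq.append(pool[int(rng.integers(0, len(pool)))])
    return "".join(seq)


def _structure_from_arrays(sid: str, seq: str, xyz: np.ndarray, indices=None) -> StructureCoords:
    cb = _sidechain_positions(xyz)
    if indices is None:
        indices = range(1, len(xyz) + 1)
    residues = [
        Residue(
            index=int(idx),
            aa=seq[k],
            atoms=[("CA", *map(float, xyz[k])), ("CB", *map(float, cb[k]))],
        )
        for k, idx in enumerate(indices)
    ]
    return StructureCoords(id=sid, residues=residues)


def make_toy_structure(
    n_res: int, seed: int | np.random.Generator, structure_id: str = "toy"
) -> tuple[StructureCoords, str]:
    """Generate a toy protein: self-avoiding CA trace with helix/strand/coil
    segments, one pseudo side-chain heavy atom per residue, and a sequence
    sampled with composition bias by secondary structure and burial.

    Returns ``(structure, secondary_structure_string)``.
    """
    if not 20 <= n_res <= 600:
        raise ValueError("n_res must lie in [20, 600]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(25):
        ss = _sample_segments(n_res, rng)
        xyz = _build_trace(n_res, ss, rng)
        if xyz is not None:
            seq = _sample_sequence(ss, _burial_labels(xyz), rng)
            return _structure_from_arrays(structure_id, seq, xyz), "".join(ss)
    raise RuntimeError(f"could not build a clash-free {n_res}-residue trace")


# ---------------------------------------------------------------------------
# decoys and templates
# ---------------------------------------------------------------------------

PERTURB_SEGMENT = 15  # residues per rigid jitter block


def _perturb_coords(xyz: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Segment-wise rigid jitter plus per-atom Gaussian noise."""
    from scipy.spatial.transform import Rotation

    out = xyz.copy()
    n = len(xyz)
    for start in range(0, n, PERTURB_SEGMENT):
        seg = slice(start, min(start + PERTURB_SEGMENT, n))
        centroid = out[seg].mean(axis=0)
        angle = rng.normal(0.0, math.radians(min(4.0 * magnitude, 60.0)))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        shift = rng.normal(0.0, 0.5 * magnitude, size=3)
        out[seg] = (out[seg] - centroid) @ rot.T + centroid + shift
    out += rng.normal(0.0, 0.25 * magnitude, size=out.shape)
    return out


def perturb_structure(
    native: StructureCoords,
    magnitude: float,
    seed: int | np.random.Generator,
    decoy_id: str | None = None,
) -> tuple[StructureCoords, float]:
    """Controlled decoy: the native under segment-wise rigid jitter and
    per-atom Gaussian noise of the given magnitude (Angstrom).

    Returns the decoy and its true TM-score to the native.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xyz = native.ca_array()
    new_xyz = _perturb_coords(xyz, magnitude, rng) if magnitude > 0 else xyz.copy()
    decoy = _structure_from_arrays(
        decoy_id or f"{native.id}_decoy", native.sequence, new_xyz,
        indices=native.residue_indices(),
    )
    tm = 1.0 if magnitude == 0 else tm_score_coords(new_xyz, xyz, len(native))
    return decoy, tm


def make_template(
    native: StructureCoords,
    magnitude: float,
    rng: np.random.Generator,
    template_id: str,
    identity: float = 0.25,
    max_deletion_fraction: float = 0.15,
) -> BenchmarkTemplate:
    """A template for the native: perturbed coordinates, short deletions,
    renumbered 1..Lq, and a mostly mutated sequence.

    The ground-truth alignment maps every kept target position to its
    template position; the true TM-score is computed over those pairs and
    normalised by the target length.
    """
    n = len(native)
    xyz = _perturb_coords(native.ca_array(), magnitude, rng)
    keep = np.ones(n, dtype=bool)
    n_dels = int(rng.integers(0, 4))
    budget = int(max_deletion_fraction * n)
    for _ in range(n_dels):
        if budget <= 0:
            break
        length = int(rng.integers(1, min(8, budget) + 1))
        start = int(rng.integers(0, n - length))
        keep[start : start + length] = False
        budget -= length
    kept = np.flatnonzero(keep)
    if len(kept) < 20:
        kept = np.arange(n)
    seq = []
    for k in kept:
        if rng.uniform() < identity:
            seq.append(native.sequence[k])
        else:
            seq.append(ALL_AA[int(rng.integers(0, 20))])
    structure = _structure_from_arrays(template_id, "".join(seq), xyz[kept])
    pairs = [(int(k) + 1, pos + 1) for pos, k in enumerate(kept)]
    tm = tm_score_coords(xyz[kept], native.ca_array()[kept], n)
    return BenchmarkTemplate(
        id=template_id, structure=structure, true_tm=tm, reference_pairs=pairs
    )


# ---------------------------------------------------------------------------
# mock threading methods
# ---------------------------------------------------------------------------


def _score_from_signal(signal: float, score_type: str) -> float:
    if score_type == "zscore":
        return -2.0 + 14.0 * signal
    if score_type == "evalue":
        return float(10.0 ** (-12.0 * signal))
    if score_type == "probability":
        return float(1.0 / (1.0 + math.exp(-6.0 * (signal - 0.45))))
    raise ValueError(f"unknown score_type {score_type!r}")


def _noisy_alignment(
    pairs: list[tuple[int, int]],
    align_noise: float,
    template_length: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    noisy: list[tuple[int, int]] = []
    for t, q in pairs:
        if rng.uniform() < align_noise:
            if rng.uniform() < 0.5:
                continue  # deleted
            q = q + int(rng.integers(1, 4)) * (1 if rng.uniform() < 0.5 else -1)
        noisy.append((t, q))
    # repair monotonicity / bounds after shifting
    out: list[tuple[int, int]] = []
    prev_q = 0
    for t, q in noisy:
        if 1 <= q <= template_length and q > prev_q:
            out.append((t, q))
            prev_q = q
    return out


def simulate_threader(
    true_tm: float,
    reference_pairs: list[tuple[int, int]],
    template_length: int,
    method: MethodSpec,
    template_id: str,
    rng: np.random.Generator,
    library: str = "chain",
) -> ThreadingHit | None:
    """One mock threading hit, or ``None`` when the method fails to detect
    the template.

    The raw score is a monotone map of ``rho * TM + (1 - rho) * noise`` onto
    the declared score scale; the alignment is the ground-truth map with a
    fraction ``align_noise`` of pairs shifted by 1-3 template positions or
    deleted.  Detection failure probability is logistic in (0.4 - TM), which
    reproduces the fold-recognition regime where weak templates are missed.
    """
    p_omit = 0.9 / (1.0 + math.exp(-5.0 * (0.4 - true_tm)))
    omitted = rng.uniform() < p_omit
    signal = method.rho * true_tm + (1.0 - method.rho) * rng.uniform()
    alignment = _noisy_alignment(reference_pairs, method.align_noise, template_length, rng)
    if omitted or len(alignment) < 5:
        return None
    return ThreadingHit(
        method=method.name,
        template_id=template_id,
        library=library,
        raw_score=_score_from_signal(signal, method.score_type),
        score_type=method.score_type,
        alignment=alignment,
    )


# ---------------------------------------------------------------------------
# full benchmark
# ---------------------------------------------------------------------------


def default_methods(n_methods: int, config: BenchmarkConfig) -> list[MethodSpec]:
    rhos = np.linspace(config.rho_range[1], config.rho_range[0], n_methods)
    return [
        MethodSpec(
            name=f"sim{k:02d}",
            score_type=config.score_types[k % len(config.score_types)],
            rho=float(rhos[k]),
            align_noise=config.alignment_noise,
        )
        for k in range(n_methods)
    ]


def build_benchmark(
    n_targets: int,
    n_methods: int = 5,
    config: BenchmarkConfig | None = None,
    seed: int = 0,
) -> SyntheticBenchmark:
    """A full labelled benchmark: per-target template pools spanning a wide
    TM range, mock hits per method, native contact sets and decoy model
    sets, all reproducible from one seed."""
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    methods = default_methods(n_methods, config)
    targets: dict[str, BenchmarkTarget] = {}
    hits: dict[str, list[ThreadingHit]] = {}
    for t in range(n_targets):
        tid = f"t{t:03d}"
        n_res = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        native, _ = make_toy_structure(n_res, rng, structure_id=tid)
        sequence = TargetSequence(id=tid, residues=native.sequence)
        templates: dict[str, BenchmarkTemplate] = {}
        target_hits: list[ThreadingHit] = []
        for k in range(config.n_templates):
            qid = f"{tid}_q{k:02d}"
            magnitude = float(
                rng.uniform(*config.template_magnitude_range)
            )
            tpl = make_template(
                native,
                magnitude,
                rng,
                qid,
                identity=config.template_identity,
                max_deletion_fraction=config.max_deletion_fraction,
            )
            templates[qid] = tpl
            for method in methods:
                hit = simulate_threader(
                    tpl.true_tm,
                    tpl.reference_pairs,
                    len(tpl.structure),
                    method,
                    qid,
                    rng,
                )
                if hit is not None:
                    target_hits.append(hit)
        decoys = []
        mags = np.linspace(*config.decoy_magnitude_range, config.n_decoys)
        for k in range(config.n_decoys):
            decoy, tm = perturb_structure(
                native, float(mags[k]), rng, decoy_id=f"{tid}_m{k:02d}"
            )
            decoys.append(BenchmarkDecoy(id=decoy.id, structure=decoy, true_tm=tm))
        targets[tid] = BenchmarkTarget(
            sequence=sequence,
            native=native,
            contacts=extract_contacts(native),
            templates=templates,
            decoys=decoys,
        )
        hits[tid] = target_hits
    return SyntheticBenchmark(
        targets=targets, hits=hits, methods=methods, seed=seed, config=config
    )


# ---------------------------------------------------------------------------
# ranking benchmark (feature-level decoy sets)
# ---------------------------------------------------------------------------

#: Noise scale (in TM units) of each ranking feature around the latent model
#: quality; no single feature is as informative as their combination.
RANK_FEATURE_NOISE = {
    "alignment_conf": 0.07,
    "coverage": 0.10,
    "psipred_match": 0.12,
    "burial": 0.15,
    "secstr": 0.20,
    "fraction_or_tmscore": 0.10,
}

#: Observation noise of the true TM-score around the latent quality.
RANK_TM_NOISE = 0.08


def make_rank_benchmark(
    n_targets: int = 40,
    models_per_target: int = 8,
    seed: int = 0,
    tm_noise: float = RANK_TM_NOISE,
):
    """Per-model feature table for the ranking/confidence stage.

    Each model has a latent quality q ~ U(0.2, 0.9); every feature is q plus
    feature-specific Gaussian noise (bounded features clipped to [0, 1]) and
    the recorded true TM-score is q plus observation noise of width
    ``tm_noise``.  Returns a pandas DataFrame with one row per model.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_targets):
        tid = f"t{t:03d}"
        for m in range(models_per_target):
            q = float(rng.uniform(0.2, 0.9))
            row = {"target_id": tid, "model_id": f"{tid}_m{m:02d}"}
            for name, sigma in RANK_FEATURE_NOISE.items():
                v = q + float(rng.normal(0.0, sigma))
                if name in ("alignment_conf", "coverage", "psipred_match", "fraction_or_tmscore"):
                    v = min(max(v, 0.0), 1.0)
                row[name] = v
            row["true_tm"] = min(max(q + float(rng.normal(0.0, tm_noise)), 0.0), 1.0)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_benchmark(bench: SyntheticBenchmark, out_dir: str | Path) -> None:
    """Serialize a benchmark to a directory layout consumed by the CLI.

    Layout: ``targets.fasta``, ``natives/``, ``templates/``, ``decoys/``
    (PDB), ``hits/<target>.tsv`` and ``manifest.json`` with all ground-truth
    labels.  Output is byte-deterministic for a fixed benchmark.
    """
    out = Path(out_dir)
    for sub in ("natives", "templates", "decoys", "hits"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    write_fasta(out / "targets.fasta", [bench.targets[t].sequence for t in bench.target_ids()])
    manifest: dict = {
        "seed": bench.seed,
        "methods": [
            {
                "name": m.name,
                "score_type": m.score_type,
                "rho": m.rho,
                "align_noise": m.align_noise,
            }
            for m in bench.methods
        ],
        "targets": {},
    }
    for tid in bench.target_ids():
        tgt = bench.targets[tid]
        write_structure(out / "natives" / f"{tid}.pdb", tgt.native)
        write_threading_hits(out / "hits" / f"{tid}.tsv", bench.hits[tid])
        entry: dict = {
            "length": len(tgt.native),
            "templates": {},
            "decoys": {d.id: d.true_tm for d in tgt.decoys},
            "contacts": sorted([c.i, c.j] for c in tgt.contacts),
        }
        for qid in sorted(tgt.templates):
            tpl = tgt.templates[qid]
            write_structure(out / "templates" / f"{qid}.pdb", tpl.structure)
            entry["templates"][qid] = {
                "true_tm": tpl.true_tm,
                "reference_pairs": [[t, q] for t, q in tpl.reference_pairs],
            }
        for decoy in tgt.decoys:
            write_structure(out / "decoys" / f"{decoy.id}.pdb", decoy.structure)
        manifest["targets"][tid] = entry
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_benchmark(in_dir: str | Path) -> SyntheticBenchmark:
    """Load a serialized benchmark; inverse of :func:`write_benchmark`."""
    src = Path(in_dir)
    with open(src / "manifest.json") as fh:
        manifest = json.load(fh)
    methods = [MethodSpec(**m) for m in manifest["methods"]]
    sequences = {s.id: s for s in read_fasta(src / "targets.fasta")}
    targets: dict[str, BenchmarkTarget] = {}
    hits: dict[str, list[ThreadingHit]] = {}
    for tid, entry in manifest["targets"].items():
        native = read_structure(src / "natives" / f"{tid}.pdb")
        native.id = tid
        templates = {}
        for qid, tinfo in entry["templates"].items():
            structure = read_structure(src / "templates" / f"{qid}.pdb")
            structure.id = qid
            templates[qid] = BenchmarkTemplate(
                id=qid,
                structure=structure,
                true_tm=float(tinfo["true_tm"]),
                reference_pairs=[(int(t), int(q)) for t, q in tinfo["reference_pairs"]],
            )
        decoys = []
        for did, tm in entry["decoys"].items():
            structure = read_structure(src / "decoys" / f"{did}.pdb")
            structure.id = did
            decoys.append(BenchmarkDecoy(id=did, structure=structure, true_tm=float(tm)))
        targets[tid] = BenchmarkTarget(
            sequence=sequences[tid],
            native=native,
            contacts={ContactRecord(i=i, j=j, label=True) for i, j in entry["contacts"]},
            templates=templates,
            decoys=decoys,
        )
        hits[tid] = read_threading_hits(src / "hits" / f"{tid}.tsv")
    return SyntheticBenchmark(
        targets=targets, hits=hits, methods=methods, seed=int(manifest["seed"])
    )
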