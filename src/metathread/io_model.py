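"""Core domain types and readers/writers for every format the toolkit touches.

Conventions
-----------
* All public residue numbering is 1-based and inclusive (PDB convention);
  internal numpy arrays are 0-based and never leak through the API.
* Target sequences come from FASTA; template/model coordinates from a
  deliberately small PDB dialect (ATOM records, one chain, first MODEL,
  first altloc, no HETATM, hydrogens dropped).
* Per-method threading results travel in a tab-separated exchange format,
  one record per (method, template) hit with an explicit aligned-pair list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_1to3
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = set(AMINO_ACIDS) | {"X"}

#: Target length range the pipeline was designed for; outside it we warn.
TARGET_LENGTH_RANGE = (50, 600)

SCORE_TYPES = ("zscore", "evalue", "probability")
LIBRARIES = ("chain", "domain")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TargetSequence:
    """A target amino-acid sequence (one-letter codes, 20 canonical + X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )
        lo, hi = TARGET_LENGTH_RANGE
        if not lo <= len(self.residues) <= hi:
            logger.warning(
                "target %s has length %d outside the designed range %d-%d",
                self.id, len(self.residues), lo, hi,
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Residue:
    """One residue: 1-based index, one-letter type, named heavy atoms."""

    index: int
    aa: str
    atoms: list[tuple[str, float, float, float]]

    def atom(self, name: str) -> tuple[float, float, float]:
        for a, x, y, z in self.atoms:
            if a == name:
                return (x, y, z)
        raise KeyError(f"residue {self.index} has no atom {name!r}")


@dataclass
class StructureCoords:
    """Labelled heavy-atom coordinates of one chain or model.

    Invariants: residue indices strictly increasing, every residue carries a
    CA atom, all coordinates finite.
    """

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        prev = None
        for res in self.residues:
            if prev is not None and res.index <= prev:
                raise ValueError(
                    f"structure {self.id}: residue indices not strictly "
                    f"increasing at {res.index}"
                )
            prev = res.index
            names = [a[0] for a in res.atoms]
            if "CA" not in names:
                raise ValueError(
                    f"structure {self.id}: residue {res.index} lacks a CA atom"
                )
            for _, x, y, z in res.atoms:
                if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
                    raise ValueError(
                        f"structure {self.id}: non-finite coordinate in residue "
                        f"{res.index}"
                    )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_array(self):
        """CA coordinates as an (L, 3) float array, chain order."""
        import numpy as np

        return np.array([r.atom("CA") for r in self.residues], dtype=float)

    def residue_indices(self) -> list[int]:
        return [r.index for r in self.residues]


def _check_pairs_monotone(pairs: Sequence[tuple[int, int]], context: str) -> None:
    seen_t, seen_q = set(), set()
    prev_t, prev_q = 0, 0
    for t, q in pairs:
        if t < 1 or q < 1:
            raise ValueError(f"{context}: aligned positions must be 1-based, got ({t},{q})")
        if t <= prev_t or q <= prev_q:
            raise ValueError(
                f"{context}: aligned pairs must be strictly increasing in both "
                f"coordinates (crossing at ({t},{q}))"
            )
        if t in seen_t or q in seen_q:
            raise ValueError(f"{context}: position reused at ({t},{q})")
        seen_t.add(t)
        seen_q.add(q)
        prev_t, prev_q = t, q


@dataclass
class ThreadingHit:
    """One threading method's assessment of one target/template pair."""

    method: str
    template_id: str
    library: str
    raw_score: float
    score_type: str
    alignment: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"unknown score_type {self.score_type!r}")
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}")
        if self.score_type == "evalue" and self.raw_score < 0:
            raise ValueError("E-value scores must be >= 0")
        if self.score_type == "probability" and not 0.0 <= self.raw_score <= 1.0:
            raise ValueError("probability scores must lie in [0, 1]")
        _check_pairs_monotone(
            self.alignment, f"hit {self.method}/{self.template_id}"
        )


@dataclass
class PairAlignment:
    """A target-to-template alignment with per-pair confidences.

    ``coverage`` is the fraction of target residues aligned,
    |pairs| / target_length.
    """

    target_id: str
    template_id: str
    pairs: list[tuple[int, int]]
    per_pair_confidence: list[float]
    target_length: int
    template_length: int = 0
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        _check_pairs_monotone(self.pairs, f"alignment {self.target_id}/{self.template_id}")
        if len(self.per_pair_confidence) != len(self.pairs):
            raise ValueError("per_pair_confidence length must match pairs")
        for c in self.per_pair_confidence:
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0, 1]")
        if self.target_length <= 0:
            raise ValueError("target_length must be positive")
        self.coverage = len(self.pairs) / self.target_length

    @property
    def mean_confidence(self) -> float:
        if not self.per_pair_confidence:
            return 0.0
        return float(sum(self.per_pair_confidence) / len(self.per_pair_confidence))

    def mapping(self) -> dict[int, int]:
        """Target position -> template position."""
        return dict(self.pairs)


#: Minimum sequence separation for a long-range contact: at least four
#: intervening residues, i.e. |i - j| >= 5.
CONTACT_MIN_SEPARATION = 5
#: Heavy-atom distance cutoff defining a contact, in Angstrom.
CONTACT_DISTANCE_CUTOFF = 4.5


@dataclass(frozen=True)
class ContactRecord:
    """A residue-residue contact, predicted or observed.

    Equality and hashing consider the (i, j) pair only, so sets of records
    behave like sets of unordered residue pairs.
    """

    i: int
    j: int
    probability: float = field(default=1.0, compare=False)
    label: bool | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)
        if self.j - self.i < CONTACT_MIN_SEPARATION:
            raise ValueError(
                f"contact ({self.i},{self.j}) violates the minimum sequence "
                f"separation of {CONTACT_MIN_SEPARATION}"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("contact probability must lie in [0, 1]")


#: Feature order of the per-model ranking vector (externals come after).
RANK_FEATURES = (
    "alignment_conf",
    "coverage",
    "psipred_match",
    "burial",
    "secstr",
    "fraction_or_tmscore",
)

#: Optional external per-model score columns accepted from a feature table.
EXTERNAL_FEATURES = ("dope", "dfire", "ga341", "tasser_fract", "tasser_dens", "tasser_ene")


@dataclass
class RankFeatureVector:
    """Per-model feature set consumed by the ranking and confidence models."""

    model_id: str
    alignment_conf: float
    coverage: float
    psipred_match: float
    burial: float
    secstr: float
    fraction_or_tmscore: float
    external: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in RANK_FEATURES:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"rank feature {name!r} missing or non-finite")
        if not 0.0 <= self.psipred_match <= 1.0:
            raise ValueError("psipred_match must lie in [0, 1]")
        unknown = set(self.external) - set(EXTERNAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown external feature columns: {sorted(unknown)}")

    def as_row(self, external_columns: Sequence[str] = ()) -> list[float]:
        row = [getattr(self, name) for name in RANK_FEATURES]
        for col in external_columns:
            if col not in self.external:
                raise ValueError(f"external feature {col!r} absent for {self.model_id}")
            row.append(self.external[col])
        return row


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[TargetSequence]:
    """Read a FASTA file into :class:`TargetSequence` records.

    Whitespace is stripped and residues are uppercased.  An empty file or a
    record containing letters outside the 20 canonical amino acids plus X is
    rejected with a :class:`FormatError` naming the offending line.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out: list[TargetSequence] = []
    for rec in records:
        seq = str(rec.seq).upper().replace(" ", "")
        bad = set(seq) - VALID_LETTERS
        if bad:
            lineno = _find_offending_line(path, bad)
            raise FormatError(
                f"{path}:{lineno}: invalid residue letter(s) {sorted(bad)} in "
                f"record {rec.id!r}"
            )
        out.append(TargetSequence(id=rec.id, residues=seq))
    return out


def _find_offending_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return lineno
    return 0


def write_fasta(path: str | Path, sequences: Iterable[TargetSequence]) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PDB (read subset + minimal writer)
# ---------------------------------------------------------------------------


def read_structure(path: str | Path, chain: str = "A") -> StructureCoords:
    """Read one chain of a PDB file into :class:`StructureCoords`.

    Only ATOM records of the first MODEL are used; hydrogens are dropped, the
    first altloc is kept, and residues lacking a CA atom are skipped with a
    logged warning.  Requesting an absent chain raises a :class:`FormatError`
    listing the chains present.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    model = next(structure.get_models())
    chains = {c.id for c in model}
    if chain not in chains:
        raise FormatError(
            f"{path}: chain {chain!r} not present; available chains: {sorted(chains)}"
        )
    residues: list[Residue] = []
    for res in model[chain]:
        hetfield, resseq, icode = res.id
        if hetfield.strip():
            continue  # HETATM / water
        if icode.strip():
            continue  # insertion codes out of scope
        atoms: list[tuple[str, float, float, float]] = []
        for atom in res:
            if atom.is_disordered():
                atom = atom.disordered_get_list()[0]  # first altloc
            if (atom.element or "").upper() in ("H", "D"):
                continue
            x, y, z = (float(v) for v in atom.coord)
            atoms.append((atom.get_name(), x, y, z))
        names = [a[0] for a in atoms]
        if "CA" not in names:
            logger.warning(
                "%s chain %s: residue %s lacks CA, dropped", path.name, chain, resseq
            )
            continue
        aa = protein_letters_3to1.get(res.get_resname().upper(), "X")
        residues.append(Residue(index=int(resseq), aa=aa, atoms=atoms))
    return StructureCoords(id=f"{path.stem}_{chain}", residues=residues)


_1TO3 = {k: v.upper() for k, v in protein_letters_1to3.items()}


def write_structure(path: str | Path, structure: StructureCoords, chain: str = "A") -> None:
    """Write a structure as plain PDB ATOM records (single chain, no TER gaps).

    The fixed-format output is byte-deterministic, which the reproducibility
    guarantees of the synthetic benchmark rely on.
    """
    lines = []
    serial = 1
    for res in structure.residues:
        resname = _1TO3.get(res.aa, "UNK")
        for name, x, y, z in res.atoms:
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pdb_name:4s} {resname:3s} {chain:1s}"
                f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# threading-hit exchange TSV
# ---------------------------------------------------------------------------

_HIT_COLUMNS = ("method", "template_id", "library", "score_type", "raw_score", "pairs")


def _format_pairs(pairs: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{t}:{q}" for t, q in pairs)


def _parse_pairs(text: str, context: str) -> list[tuple[int, int]]:
    if not text or text == "-":
        return []
    pairs = []
    for token in text.split(";"):
        try:
            t, q = token.split(":")
            pairs.append((int(t), int(q)))
        except ValueError as exc:
            raise FormatError(f"{context}: malformed pair token {token!r}") from exc
    return pairs


def write_threading_hits(path: str | Path, hits: Iterable[ThreadingHit]) -> None:
    """Write hits in the exchange TSV dialect (deterministic column order)."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.method,
                        h.template_id,
                        h.library,
                        h.score_type,
                        repr(float(h.raw_score)),
                        _format_pairs(h.alignment) or "-",
                    ]
                )
                + "\n"
            )


def read_threading_hits(path: str | Path) -> list[ThreadingHit]:
    """Read the exchange TSV; alignments are validated monotone on load."""
    path = Path(path)
    hits: list[ThreadingHit] = []
    with open(path) as fh:
        for recno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_HIT_COLUMNS):
                raise FormatError(
                    f"{path}: record {recno}: expected {len(_HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            method, template_id, library, score_type, raw_score, pairs_text = fields
            pairs = _parse_pairs(pairs_text, f"{path}: record {recno}")
            try:
                hit = ThreadingHit(
                    method=method,
                    template_id=template_id,
                    library=library,
                    raw_score=float(raw_score),
                    score_type=score_type,
                    alignment=pairs,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: record {recno}: {exc}") from exc
            hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# alignment / contact / rank reports
# ---------------------------------------------------------------------------


def write_alignments(path: str | Path, alignments: Iterable[PairAlignment]) -> None:
    with open(path, "w") as fh:
        fh.write("# target_id\ttemplate_id\ttarget_length\ttemplate_length\tpairs\tconfidences\n")
        for aln in alignments:
            fh.write(
                "\t".join(
                    [
                        aln.target_id,
                        aln.template_id,
                        str(aln.target_length),
                        str(aln.template_length),
                        _format_pairs(aln.pairs) or "-",
                        ";".join(repr(float(c)) for c in aln.per_pair_confidence) or "-",
                    ]
                )
                + "\n"
            )


def read_alignments(path: str | Path) -> list[PairAlignment]:
    path = Path(path)
    out: list[PairAlignment] = []
    with open(path) as fh:
        for recno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(f"{path}: record {recno}: expected 6 columns")
            tid, qid, tlen, qlen, pairs_text, conf_text = fields
            pairs = _parse_pairs(pairs_text, f"{path}: record {recno}")
            confs = (
                [float(c) for c in conf_text.split(";")] if conf_text != "-" else []
            )
            out.append(
                PairAlignment(
                    target_id=tid,
                    template_id=qid,
                    pairs=pairs,
                    per_pair_confidence=confs,
                    target_length=int(tlen),
                    template_length=int(qlen),
                )
            )
    return out


def write_contacts(path: str | Path, contacts: Iterable[ContactRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("# i\tj\tprobability\n")
        for c in sorted(contacts, key=lambda c: (c.i, c.j)):
            fh.write(f"{c.i}\t{c.j}\t{repr(float(c.probability))}\n")


def read_contacts(path: str | Path) -> list[ContactRecord]:
    path = Path(path)
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            i, j, p = line.split("\t")
            out.append(ContactRecord(i=int(i), j=int(j), probability=float(p)))
    return out
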