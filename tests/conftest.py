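import numpy as np
import pytest

from metathread.io_model import Residue, StructureCoords
from metathread.synthetic import build_benchmark, make_toy_structure


@pytest.fixture(scope="session")
def toy_structure():
    """One reproducible 60-residue toy protein."""
    structure, ss = make_toy_structure(60, seed=1234)
    return structure, ss


@pytest.fixture(scope="session")
def small_benchmark():
    """A small but complete labelled benchmark shared across tests."""
    return build_benchmark(12, 4, seed=42)


def structure_from_ca(ca, sequence=None, sid="fix", indices=None):
    """Helper: build a CA-only structure from an (N, 3) array."""
    ca = np.asarray(ca, dtype=float)
    n = len(ca)
    seq = sequence or "A" * n
    idx = indices or range(1, n + 1)
    residues = [
        Residue(index=int(i), aa=seq[k], atoms=[("CA", *map(float, ca[k]))])
        for k, i in enumerate(idx)
    ]
    return StructureCoords(id=sid, residues=residues)


@pytest.fixture
def structure_factory():
    return structure_from_ca
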