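import numpy as np
import pytest

from pymotif import ProteinRecord
from pymotif.records import ALPHABET, STANDARD_RESIDUES

ALPHABET_STR = "".join(sorted(ALPHABET))


def naive_scan(sequence: str, pattern) -> list:
    """Sliding-window oracle: check every start against the constraint list."""
    plen = len(pattern.positions)
    found = []
    for s in range(len(sequence) - plen + 1):
        if all(
            p is None or sequence[s + i] == p
            for i, p in enumerate(pattern.positions)
        ):
            found.append((s, pattern.name, sequence[s : s + plen]))
    return found


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET_STR), size=length))


def random_pattern_spec(rng: np.random.Generator) -> str:
    """A random motif spec with >= 1 fixed position, length 3-6."""
    while True:
        length = int(rng.integers(3, 7))
        spec = "".join(
            "x" if rng.random() < 0.4 else str(rng.choice(list(STANDARD_RESIDUES)))
            for _ in range(length)
        )
        if spec != "x" * length:
            return spec


@pytest.fixture
def enac_record() -> ProteinRecord:
    """The native ENaC-derived template peptide with its single PPxY motif."""
    return ProteinRecord("ENaC", "TAPPPAYATLG")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
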