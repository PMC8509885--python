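"""Core sequence record type and the amino-acid alphabet.

Sequences are stored uppercase over the 20 standard residues plus the
ambiguity/rare codes B, J, O, U, X, Z that occur in real proteome FASTA
dumps. Gap characters, digits and whitespace are rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass

STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_RESIDUES: str = "BJOUXZ"
ALPHABET: frozenset = frozenset(STANDARD_RESIDUES + AMBIGUOUS_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """One identified amino-acid sequence.

    Parameters
    ----------
    identifier : str
        Accession or gene symbol; unique within a loaded collection.
    sequence : str
        Residues over the alphabet above; lowercase input is uppercased.
    description : str
        Free-text remainder of the FASTA header (may be empty).
    """

    identifier: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("record identifier must be non-empty")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.identifier}: sequence must be non-empty")
        for pos, ch in enumerate(seq):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{self.identifier}: illegal character {ch!r} at position {pos + 1}"
                )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)
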