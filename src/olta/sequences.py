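"""Small shared sequence utilities.

Everything operates on plain uppercase DNA strings; biopython does the actual
complementing/translating so the genetic code is never hand-rolled.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

_STANDARD_TABLE = unambiguous_dna_by_id[1]

#: amino acid (one-letter) -> sorted tuple of synonymous codons, standard code
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD_TABLE.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

AMINO_ACIDS = frozenset(AA_TO_CODONS)


class SequenceError(ValueError):
    """Raised for malformed sequence input (wrong alphabet or length)."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    if len(seq) % 3:
        raise SequenceError(f"length {len(seq)} is not a multiple of 3")
    return str(Seq(seq).translate())


def check_dna(seq: str, *, name: str = "sequence", allow_n: bool = False) -> str:
    """Uppercase ``seq`` and verify it is plain DNA; return the uppercase form."""
    up = seq.upper()
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    bad = set(up) - alphabet
    if bad:
        raise SequenceError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return up


def check_protein(seq: str, *, name: str = "helix") -> str:
    up = seq.upper()
    bad = set(up) - AMINO_ACIDS
    if bad:
        raise SequenceError(f"{name} contains invalid residues: {sorted(bad)}")
    return up
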