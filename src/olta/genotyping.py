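"""Classification of sequenced reads against a wild-type amplicon.

ZFN cutting followed by error-prone non-homologous end joining leaves
substitutions, deletions and insertions at the target site.  Each read is
globally aligned to the wild-type amplicon with affine gap penalties (so a
contiguous deletion -- the dominant NHEJ outcome -- aligns as a single gap)
and the aligned columns are tallied into an edit call such as ``"3 D, 2 S"``.
A simple in-silico T7 endonuclease I assay predicts the two cleavage-fragment
lengths of a wild-type/mutant heteroduplex.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .sequences import SequenceError, check_dna


@dataclass(frozen=True)
class AlignmentParams:
    """Affine-gap global alignment scores (biopython sign convention).

    Defaults (match +1, mismatch -1, gap open -4, gap extend -0.5) make a
    single k-nt gap cheaper than scattering k substitutions for k >= 2, so
    clean NHEJ deletions/insertions come out as one contiguous event.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    open_gap_score: float = -4.0
    extend_gap_score: float = -0.5

    def __post_init__(self) -> None:
        if not self.open_gap_score < self.extend_gap_score <= 0:
            raise ValueError("need gap-open penalty > gap-extend penalty >= 0")
        if not (self.match_score > 0 >= self.mismatch_score):
            raise ValueError("need match_score > 0 >= mismatch_score")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match_score
        aligner.mismatch_score = self.mismatch_score
        aligner.open_gap_score = self.open_gap_score
        aligner.extend_gap_score = self.extend_gap_score
        return aligner


DEFAULT_PARAMS = AlignmentParams()


def align_pair(wt: str, read: str, params: AlignmentParams = DEFAULT_PARAMS):
    """Global affine alignment of a read to the wild-type sequence.

    Case-insensitive (published genotype tables use lowercase for display
    only).  Of the co-optimal alignments the aligner's first is taken, a
    deterministic tie-break that places gaps leftmost-first in practice.
    """
    wt = check_dna(wt, name="wt")
    read = check_dna(read, name="read")
    if not wt or not read:
        raise SequenceError("alignment inputs must be non-empty")
    return params.aligner().align(wt, read)[0]


@dataclass(frozen=True)
class EditCall:
    n_sub: int
    n_del: int
    n_ins: int

    @property
    def is_wt(self) -> bool:
        return (self.n_sub, self.n_del, self.n_ins) == (0, 0, 0)

    @property
    def label(self) -> str:
        """Canonical genotype label: nonzero counts as ``"<n> S/D/I"`` joined
        by commas, largest first (``"WT"`` when all zero)."""
        if self.is_wt:
            return "WT"
        parts = [
            (n, code)
            for n, code in ((self.n_sub, "S"), (self.n_del, "D"), (self.n_ins, "I"))
            if n
        ]
        parts.sort(key=lambda p: (-p[0], "SDI".index(p[1])))
        return ", ".join(f"{n} {code}" for n, code in parts)


def classify_edits(alignment) -> EditCall:
    """Tally aligned columns: mismatched pairs are substitutions, reference
    bases opposite gaps are deletions, read bases opposite gaps insertions."""
    wt_row, read_row = str(alignment[0]), str(alignment[1])
    n_sub = n_del = n_ins = 0
    for a, b in zip(wt_row, read_row):
        if a == "-":
            n_ins += 1
        elif b == "-":
            n_del += 1
        elif a != b:
            n_sub += 1
    return EditCall(n_sub=n_sub, n_del=n_del, n_ins=n_ins)


def classify_read(wt: str, read: str, params: AlignmentParams = DEFAULT_PARAMS) -> EditCall:
    """Convenience: align then classify."""
    return classify_edits(align_pair(wt, read, params))


@dataclass
class SummaryTable:
    """Examined/mutated totals plus per-genotype multiplicities."""

    examined: int = 0
    mutated: int = 0
    genotypes: Counter = field(default_factory=Counter)

    def rows(self) -> list[tuple[str, int]]:
        wt = [("WT", self.genotypes["WT"])] if "WT" in self.genotypes else []
        rest = sorted(
            (item for item in self.genotypes.items() if item[0] != "WT"),
            key=lambda kv: (-kv[1], kv[0]),
        )
        return wt + rest


def tally(calls: Sequence[EditCall]) -> SummaryTable:
    table = SummaryTable()
    for call in calls:
        table.examined += 1
        if not call.is_wt:
            table.mutated += 1
        table.genotypes[call.label] += 1
    return table


def t7e1_predict(
    wt_amplicon: str,
    mutant_amplicon: str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> Optional[tuple[int, int]]:
    """Predicted T7 endonuclease I cleavage-fragment lengths.

    The enzyme cuts a re-annealed wild-type/mutant heteroduplex next to the
    mismatch/indel bubble; the cut is placed at the first non-matching column
    of the pairwise alignment, measured in wild-type coordinates, so the two
    fragment lengths always sum to the uncut amplicon length.  Identical
    sequences form no bubble and return ``None``.
    """
    wt = check_dna(wt_amplicon, name="wt_amplicon")
    mut = check_dna(mutant_amplicon, name="mutant_amplicon")
    if wt == mut:
        return None
    alignment = align_pair(wt, mut, params)
    wt_row, mut_row = str(alignment[0]), str(alignment[1])
    consumed = 0
    for a, b in zip(wt_row, mut_row):
        if a == "-" or b == "-" or a != b:
            return consumed, len(wt) - consumed
        consumed += 1
    return None  # pragma: no cover - unreachable for unequal sequences
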