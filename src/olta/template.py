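"""Two-helix zinc-finger template model and mismatch-minimizing primer design.

The OLTA 1st PCR amplifies a short template spanning two consecutive
DNA-recognition helices of a C2H2 zinc-finger domain.  A new helix is
introduced simply by back-translating its 7 amino acids onto the primer while
keeping the primer as close as possible to the template sequence: per residue,
the synonymous codon with the fewest nucleotide differences to the template
codon is chosen.  Because residues contribute independently, the per-residue
greedy choice is the exact global optimum over all synonymous combinations.

Design constraints (both configurable):

* at most ``max_mismatch`` (default 11) differences to the template per primer;
* a perfectly complementary 3' end -- the constant 8-nt tail on forward
  primers, and a 7-nt constant anchor on reverse primers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from .registry import FWD_TAIL, MAX_NDN, REV_ANCHOR
from .sequences import AA_TO_CODONS, SequenceError, check_dna, check_protein, revcomp, translate

#: 29-nt forward cloning primer used to amplify the two-helix template;
#: its first 21 nt are the helix-1 codons, its last 8 nt the constant tail.
STANDARD_FWD_CLONING_PRIMER = "CGCTCGGATGCGCTTACCCGCCATATCCG"
#: 27-nt reverse cloning primer (3' end of the cloned 104-bp template).
STANDARD_REV_CLONING_PRIMER = "CGGGCAAGATTATCCGAGCGACTGAAG"

#: Synthetic 48-nt stand-in for the framework between the two annealing
#: regions (the real nucleotides live in a supplementary file that is supplied
#: by the user when available).  It encodes the canonical C2H2 inter-helix
#: framework peptide HIRIHTGQKPFQCRICMRNFS, with the codons at both ends
#: pinned by the cloning primers, and brings the insert to 104 nt.
SYNTHETIC_INTERNAL_FRAMEWORK = (
    "C" "ATCCACACCGGCCAGAAGCCCTTCCAGTGCCGCATCTGCATGCGC" "AA"
)


class DesignError(SequenceError):
    """A primer design violates a hard constraint.

    Carries the best achievable design in ``best`` so callers can inspect how
    far off it was.
    """

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def count_mismatches(a: str, b: str) -> int:
    """Position-wise Hamming distance, case-insensitive."""
    if len(a) != len(b):
        raise SequenceError(f"cannot compare sequences of lengths {len(a)} and {len(b)}")
    au, bu = a.upper(), b.upper()
    return sum(x != y for x, y in zip(au, bu))


def check_three_prime_anchor(primer: str, reference: str, k: int = 7) -> bool:
    """True iff the 3'-terminal ``k`` positions of primer and reference agree."""
    if len(primer) != len(reference):
        raise SequenceError("primer and reference must have equal length")
    if k <= 0:
        return True
    return primer.upper()[-k:] == reference.upper()[-k:]


@dataclass(frozen=True)
class TemplateModel:
    """The two-helix-slot zinc-finger template.

    ``fwd_ref`` is the 29-nt helix-1 annealing region (identical to the
    forward cloning primer).  ``rev_ref`` is the 29-nt helix-2 annealing
    region written on the primer strand: the 27-nt reverse cloning primer
    extended 5' by the two genomic nucleotides "GG" -- the published GAG
    reverse primer equals exactly this 29-mer with zero recorded mismatches,
    which pins the convention.  ``internal_framework`` is the segment between
    the two annealing regions on the top strand.
    """

    fwd_ref: str
    rev_ref: str
    internal_framework: str = SYNTHETIC_INTERNAL_FRAMEWORK

    def __post_init__(self) -> None:
        object.__setattr__(self, "fwd_ref", check_dna(self.fwd_ref, name="fwd_ref"))
        object.__setattr__(self, "rev_ref", check_dna(self.rev_ref, name="rev_ref"))
        object.__setattr__(
            self,
            "internal_framework",
            check_dna(self.internal_framework, name="internal_framework"),
        )
        if len(self.fwd_ref) != 29:
            raise SequenceError(f"fwd_ref must be 29 nt, got {len(self.fwd_ref)}")
        if len(self.rev_ref) != 29:
            raise SequenceError(f"rev_ref must be 29 nt, got {len(self.rev_ref)}")
        if not self.fwd_ref.endswith(FWD_TAIL):
            raise SequenceError(f"fwd_ref must end with the constant tail {FWD_TAIL}")
        if not self.rev_ref.endswith(REV_ANCHOR):
            raise SequenceError(f"rev_ref must end with the constant anchor {REV_ANCHOR}")
        translate(self.fwd_ref[:21])  # must be a clean 7-aa frame

    # -- derived views ----------------------------------------------------
    @property
    def fwd_codon_ref(self) -> str:
        """Template codons of helix slot 1 (top strand)."""
        return self.fwd_ref[:21]

    @cached_property
    def _rev_top(self) -> str:
        """rev_ref mapped onto the top strand: 7-nt leading framework,
        21 helix-2 codons, 1 trailing framework nt."""
        return revcomp(self.rev_ref)

    @property
    def rev_codon_ref(self) -> str:
        """Template codons of helix slot 2 (top strand)."""
        return self._rev_top[7:28]

    @property
    def rev_leading_framework(self) -> str:
        return self._rev_top[:7]

    @property
    def rev_trailing_nt(self) -> str:
        return self._rev_top[28]

    @property
    def helix1(self) -> str:
        return translate(self.fwd_codon_ref)

    @property
    def helix2(self) -> str:
        return translate(self.rev_codon_ref)

    @property
    def insert_seq(self) -> str:
        """The cloned template region (104 nt with the default framework):
        forward annealing region + internal framework + reverse-complement of
        the 27-nt reverse cloning primer."""
        return self.fwd_ref + self.internal_framework + self._rev_top[:27]

    @property
    def total_length(self) -> int:
        return len(self.insert_seq)

    @property
    def amplicon_seq(self) -> str:
        """The 1st-PCR amplicon of the template's own helices (insert + the
        2-nt genomic context carried on the reverse primer's 5' end)."""
        return self.fwd_ref + self.internal_framework + self._rev_top


def build_template(
    fwd_cloning_primer: str = STANDARD_FWD_CLONING_PRIMER,
    rev_cloning_primer: str = STANDARD_REV_CLONING_PRIMER,
    internal_framework: str | None = None,
) -> TemplateModel:
    """Construct the template model from the two cloning primers.

    ``rev_cloning_primer`` is the printed 27-mer; the reverse annealing
    reference becomes ``"GG" + rev_cloning_primer`` (29 nt).
    """
    fwd = check_dna(fwd_cloning_primer, name="forward cloning primer")
    rev = check_dna(rev_cloning_primer, name="reverse cloning primer")
    if len(fwd) != 29:
        raise SequenceError(f"forward cloning primer must be 29 nt, got {len(fwd)}")
    if len(rev) != 27:
        raise SequenceError(f"reverse cloning primer must be 27 nt, got {len(rev)}")
    kwargs = {}
    if internal_framework is not None:
        kwargs["internal_framework"] = internal_framework
    return TemplateModel(fwd_ref=fwd, rev_ref="GG" + rev, **kwargs)


@dataclass(frozen=True)
class DesignedPrimer:
    """One designed 1st-PCR primer for a 7-aa helix."""

    helix: str
    direction: str  # "fwd" | "rev"
    sequence: str
    codons: str  # the 21 chosen coding nucleotides (top strand)
    ndn: int
    anchor_ok: bool


@dataclass(frozen=True)
class DesignedPrimerPair:
    helix: str
    fwd: DesignedPrimer
    rev: DesignedPrimer

    @property
    def fwd_primer(self) -> str:
        return self.fwd.sequence

    @property
    def rev_primer(self) -> str:
        return self.rev.sequence

    @property
    def fwd_ndn(self) -> int:
        return self.fwd.ndn

    @property
    def rev_ndn(self) -> int:
        return self.rev.ndn


def _choose_codons(helix: str, codon_ref: str) -> tuple[str, int]:
    """Per-residue minimal-mismatch synonymous codons against ``codon_ref``.

    Ties are broken toward the codon lexicographically closest to the
    reference codon (smallest codon string among equal-distance choices),
    which is deterministic and seed-free.  The summed distance is the exact
    global minimum because residues are independent.
    """
    chosen: list[str] = []
    total = 0
    for i, aa in enumerate(helix):
        ref = codon_ref[3 * i : 3 * i + 3]
        best = min(AA_TO_CODONS[aa], key=lambda c: (count_mismatches(c, ref), c))
        chosen.append(best)
        total += count_mismatches(best, ref)
    return "".join(chosen), total


def design_forward_primer(
    helix: str, template: TemplateModel, max_mismatch: int = MAX_NDN
) -> DesignedPrimer:
    """Design the forward 1st-PCR primer for ``helix``.

    21 codon nucleotides minimizing mismatches to the template's helix-1
    codons, plus the constant 8-nt tail (always perfectly complementary).
    """
    helix = check_protein(helix)
    if len(helix) != 7:
        raise SequenceError(f"helix must be 7 residues, got {len(helix)}")
    codons, ndn = _choose_codons(helix, template.fwd_codon_ref)
    primer = codons + FWD_TAIL
    designed = DesignedPrimer(
        helix=helix,
        direction="fwd",
        sequence=primer,
        codons=codons,
        ndn=ndn,
        anchor_ok=check_three_prime_anchor(primer, template.fwd_ref, k=8),
    )
    if ndn > max_mismatch:
        raise DesignError(
            f"forward primer for {helix} needs {ndn} mismatches (> {max_mismatch})",
            best=designed,
        )
    return designed


def design_reverse_primer(
    helix: str, template: TemplateModel, max_mismatch: int = MAX_NDN
) -> DesignedPrimer:
    """Design the reverse 1st-PCR primer for ``helix``.

    Codons are chosen against the template's helix-2 codons; the primer is
    the reverse complement of (7-nt leading framework + 21 codon nt + 1
    framework nt), so its 3'-terminal 7 nt are the constant anchor.
    """
    helix = check_protein(helix)
    if len(helix) != 7:
        raise SequenceError(f"helix must be 7 residues, got {len(helix)}")
    codons, ndn = _choose_codons(helix, template.rev_codon_ref)
    primer = revcomp(template.rev_leading_framework + codons + template.rev_trailing_nt)
    designed = DesignedPrimer(
        helix=helix,
        direction="rev",
        sequence=primer,
        codons=codons,
        ndn=ndn,
        anchor_ok=check_three_prime_anchor(primer, template.rev_ref, k=7),
    )
    if ndn > max_mismatch:
        raise DesignError(
            f"reverse primer for {helix} needs {ndn} mismatches (> {max_mismatch})",
            best=designed,
        )
    return designed


def design_primer_pair(
    helix: str, template: TemplateModel, max_mismatch: int = MAX_NDN
) -> DesignedPrimerPair:
    return DesignedPrimerPair(
        helix=check_protein(helix),
        fwd=design_forward_primer(helix, template, max_mismatch),
        rev=design_reverse_primer(helix, template, max_mismatch),
    )


def design_shared_codons(helix: str, template: TemplateModel) -> tuple[str, int, int]:
    """One codon assignment per helix, valid for both primer directions.

    Within an overlap-extension assembly the same helix is encoded by a
    reverse primer (3' end of one fragment) and a forward primer (5' end of
    the next); the designed 21-nt overlap is exact only if both primers
    choose identical codons.  Optimizing each direction separately can pick
    different synonymous codons at the two residues where the template's
    helix-1 and helix-2 slots differ, so here the *summed* distance to both
    slot references is minimized per residue (ties to the lexicographically
    smallest codon).  Returns (codons, forward mismatches, reverse
    mismatches); a helix equal to one of the template's own helices
    reproduces that slot's codons exactly.
    """
    helix = check_protein(helix)
    if len(helix) != 7:
        raise SequenceError(f"helix must be 7 residues, got {len(helix)}")
    chosen: list[str] = []
    for i, aa in enumerate(helix):
        fwd_ref = template.fwd_codon_ref[3 * i : 3 * i + 3]
        rev_ref = template.rev_codon_ref[3 * i : 3 * i + 3]
        best = min(
            AA_TO_CODONS[aa],
            key=lambda c: (count_mismatches(c, fwd_ref) + count_mismatches(c, rev_ref), c),
        )
        chosen.append(best)
    codons = "".join(chosen)
    return (
        codons,
        count_mismatches(codons, template.fwd_codon_ref),
        count_mismatches(codons, template.rev_codon_ref),
    )


def design_array_primer_pair(
    helix: str, template: TemplateModel, max_mismatch: int = MAX_NDN
) -> DesignedPrimerPair:
    """Forward and reverse primers encoding ``helix`` with shared codons
    (see :func:`design_shared_codons`); both must stay within
    ``max_mismatch`` of their references."""
    codons, fwd_ndn, rev_ndn = design_shared_codons(helix, template)
    fwd_seq = codons + FWD_TAIL
    rev_seq = revcomp(template.rev_leading_framework + codons + template.rev_trailing_nt)
    pair = DesignedPrimerPair(
        helix=helix.upper(),
        fwd=DesignedPrimer(
            helix=helix.upper(),
            direction="fwd",
            sequence=fwd_seq,
            codons=codons,
            ndn=fwd_ndn,
            anchor_ok=check_three_prime_anchor(fwd_seq, template.fwd_ref, k=8),
        ),
        rev=DesignedPrimer(
            helix=helix.upper(),
            direction="rev",
            sequence=rev_seq,
            codons=codons,
            ndn=rev_ndn,
            anchor_ok=check_three_prime_anchor(rev_seq, template.rev_ref, k=7),
        ),
    )
    for primer in (pair.fwd, pair.rev):
        if primer.ndn > max_mismatch:
            raise DesignError(
                f"{primer.direction} primer for {helix} needs {primer.ndn} "
                f"mismatches (> {max_mismatch})",
                best=pair,
            )
    return pair
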