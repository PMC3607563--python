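"""Three-step OLTA PCR assembly, TA cloning and orientation screening.

The workflow being simulated:

1st PCR   one reaction per adjacent finger pair (ZFi-Fw + ZFi+1-Rv on the
          two-helix template) yields "partial" fragments, each running from
          one recognition helix to the next.
2nd PCR   primer-free overlap extension: fragments join wherever one
          fragment's 3' end is identical to another's 5' end -- the shared
          21-nt helix codons (plus one constant framework base) are the
          designed overlaps.
3rd PCR   end amplification with ZF1's forward and ZFn's reverse primer;
          electrophoresis of the products gives a ladder, one band at the
          intended size.
TA clone  the A-tailed 3rd-PCR product is ligated into the platform vector,
          blunt-cut with PvuII and BstZ17I and 3'-T-tailed, in either
          orientation; a colony PCR with the T3-promoter primer and the
          3rd-PCR reverse primer screens for insert presence and direction.

PCR thermodynamics are not modeled: annealing means exact sequence identity
at the positions a primer or overlap must pair, consistent with the design
rule that primer 3' ends are perfectly complementary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .registry import HelixRegistry, MAX_NDN
from .sequences import SequenceError, check_dna, revcomp, translate
from .template import (
    DesignedPrimer,
    TemplateModel,
    design_array_primer_pair,
)

#: designed overlap = the 21 helix-coding nucleotides shared by adjacent fragments
MIN_OVERLAP = 21

#: 2nd-PCR mixing recipe by finger count: fragment (i, i+1) -> microlitres
SECOND_PCR_MIX_UL: dict[int, dict[tuple[int, int], float]] = {
    4: {(1, 2): 0.5, (2, 3): 1.5, (3, 4): 0.5},
    5: {(1, 2): 0.5, (2, 3): 1.5, (3, 4): 1.5, (4, 5): 0.5},
    6: {(1, 2): 0.5, (2, 3): 0.5, (3, 4): 1.5, (4, 5): 0.5, (5, 6): 0.5},
}

T3_PROMOTER_PRIMER = "ATTAACCCTCACTAAAGGGA"
PVUII_SITE = "CAGCTG"  # blunt cut CAG^CTG
BSTZ17I_SITE = "GTATAC"  # blunt cut GTA^TAC
XHOI_SITE = "CTCGAG"


class PlanError(ValueError):
    """Reaction planning failed (finger count out of range, unknown triplet)."""


@dataclass(frozen=True)
class ReactionPlan:
    """Everything needed at the bench for one finger array."""

    triplets: tuple[str, ...]  # ZF1..ZFn
    first_pcr: tuple[tuple[str, str], ...]  # (Fw triplet, Rv triplet) per fragment
    second_pcr_mix_ul: dict[tuple[int, int], float]
    third_pcr: tuple[str, str]  # (ZF1 forward, ZFn reverse) triplet names

    @property
    def n_fingers(self) -> int:
        return len(self.triplets)

    @property
    def n_fragments(self) -> int:
        return len(self.first_pcr)

    def protocol_lines(self) -> list[str]:
        lines = [f"# {self.n_fingers}-finger array: {' '.join(self.triplets)}"]
        lines.append("1st PCR (one reaction per fragment):")
        for i, (fw, rv) in enumerate(self.first_pcr, start=1):
            lines.append(f"  ZF{i}-ZF{i + 1}: {fw}-Fw + {rv}-Rv")
        lines.append("2nd PCR (overlap extension, no primers), mix:")
        for (i, j), ul in sorted(self.second_pcr_mix_ul.items()):
            lines.append(f"  {ul} ul of ZF{i}-ZF{j} amplicon")
        lines.append(
            f"3rd PCR: {self.third_pcr[0]}-Fw + {self.third_pcr[1]}-Rv on diluted 2nd PCR"
        )
        return lines


def plan_reactions(
    array: list[str],
    registry: HelixRegistry,
    min_fingers: int = 4,
    max_fingers: int = 6,
) -> ReactionPlan:
    """Plan the three PCRs for a finger array given as triplets in ZF order
    (ZF1 first).  n fingers always need n-1 first-PCR fragments."""
    n = len(array)
    if not min_fingers <= n <= max_fingers:
        raise PlanError(f"finger count {n} outside [{min_fingers}, {max_fingers}]")
    triplets = []
    for t in array:
        triplets.append(registry.lookup(t).triplet)  # raises UnknownTripletError
    mix = SECOND_PCR_MIX_UL.get(n)
    if mix is None:
        # same pattern as published recipes: end fragments 0.5 ul, middle 1.5 ul
        mix = {
            (i, i + 1): (0.5 if i in (1, n - 1) else 1.5) for i in range(1, n)
        }
    return ReactionPlan(
        triplets=tuple(triplets),
        first_pcr=tuple((triplets[i], triplets[i + 1]) for i in range(n - 1)),
        second_pcr_mix_ul=dict(mix),
        third_pcr=(triplets[0], triplets[-1]),
    )


@dataclass(frozen=True)
class PartialFragment:
    """One 1st-PCR amplicon, spanning helix i to helix i+1."""

    index_pair: tuple[int, int]
    helix_pair: tuple[str, str]
    seq: str
    fwd_primer: str
    rev_primer: str

    @property
    def length(self) -> int:
        return len(self.seq)


def synthesize_fragment(
    template: TemplateModel,
    helix_i: str,
    helix_j: str,
    index_pair: tuple[int, int] = (1, 2),
    max_mismatch: int = MAX_NDN,
) -> PartialFragment:
    """Simulate one 1st PCR: amplicon = designed forward primer of
    ``helix_i`` + internal framework + reverse complement of the designed
    reverse primer of ``helix_j``.  Primers come from the shared-codon
    designer so a helix is encoded identically wherever it occurs and the
    21-nt overlaps between adjacent fragments are exact.  Deterministic
    given the template; every fragment has the same length."""
    fwd = design_array_primer_pair(helix_i, template, max_mismatch).fwd
    rev = design_array_primer_pair(helix_j, template, max_mismatch).rev
    seq = fwd.sequence + template.internal_framework + revcomp(rev.sequence)
    return PartialFragment(
        index_pair=index_pair,
        helix_pair=(fwd.helix, rev.helix),
        seq=seq,
        fwd_primer=fwd.sequence,
        rev_primer=rev.sequence,
    )


def synthesize_fragments(
    template: TemplateModel,
    helices: list[str],
    max_mismatch: int = MAX_NDN,
) -> list[PartialFragment]:
    """All n-1 partial fragments for an array of helices in ZF order."""
    return [
        synthesize_fragment(template, helices[i], helices[i + 1], (i + 1, i + 2), max_mismatch)
        for i in range(len(helices) - 1)
    ]


@dataclass(frozen=True)
class AssemblyProduct:
    chain: tuple[int, ...]  # fragment indices into the input list
    seq: str
    helix_order: tuple[str, ...]
    on_pathway: bool

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def n_fragments(self) -> int:
        return len(self.chain)


def _overlap_len(a: str, b: str, min_overlap: int) -> int:
    """Largest k >= min_overlap with suffix(a, k) == prefix(b, k); 0 if none."""
    for k in range(min(len(a), len(b)), min_overlap - 1, -1):
        if a[-k:] == b[:k]:
            return k
    return 0


def simulate_overlap_assembly(
    fragments: list[PartialFragment],
    min_overlap: int = MIN_OVERLAP,
    maximal_only: bool = True,
) -> list[AssemblyProduct]:
    """Enumerate overlap-extension products of the 2nd PCR.

    Builds a directed graph with an edge i->j when fragment i's 3' suffix
    exactly equals fragment j's 5' prefix over >= ``min_overlap`` nt, then
    returns chains (simple paths).  With ``maximal_only`` only chains
    extendable in neither direction are kept.  A product is on-pathway when
    its helix order equals the order implied by the input fragment list; more
    than one maximal chain means the assembly is ambiguous (a repeated helix
    creates branch points and mis-ordered products).
    """
    if not fragments:
        return []
    n = len(fragments)
    if n == 1:
        f = fragments[0]
        return [AssemblyProduct((0,), f.seq, f.helix_pair, True)]
    edges: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            k = _overlap_len(fragments[i].seq, fragments[j].seq, min_overlap)
            if k:
                edges[i].append((j, k))

    chains: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        extendable = False
        for j, _ in edges[path[-1]]:
            if j not in path:
                extendable = True
                extend(path + [j])
        if not extendable or not maximal_only:
            chains.append(tuple(path))

    for start in range(n):
        extend([start])
    if maximal_only:
        # drop chains that are contiguous sub-chains of a longer one
        def is_sub(short: tuple[int, ...], long: tuple[int, ...]) -> bool:
            if len(short) >= len(long):
                return False
            return any(
                long[k : k + len(short)] == short for k in range(len(long) - len(short) + 1)
            )

        chains = [c for c in chains if not any(is_sub(c, d) for d in chains)]
    chains = sorted(set(chains), key=lambda c: (-len(c), c))

    intended = tuple(fragments[i].helix_pair[0] for i in range(n)) + (
        fragments[-1].helix_pair[1],
    )
    products = []
    for chain in chains:
        seq = fragments[chain[0]].seq
        order = [fragments[chain[0]].helix_pair[0]]
        ok = True
        for prev, cur in zip(chain, chain[1:]):
            k = next(k for j, k in edges[prev] if j == cur)
            seq = seq + fragments[cur].seq[k:]
            order.append(fragments[cur].helix_pair[0])
            ok = ok and fragments[prev].helix_pair[1] == fragments[cur].helix_pair[0]
        order.append(fragments[chain[-1]].helix_pair[1])
        products.append(
            AssemblyProduct(
                chain=chain,
                seq=seq,
                helix_order=tuple(order),
                on_pathway=ok and tuple(order) == intended,
            )
        )
    return products


def assembly_is_ambiguous(products: list[AssemblyProduct]) -> bool:
    return len(products) > 1


@dataclass(frozen=True)
class ThirdPcrBand:
    product: AssemblyProduct
    length: int
    intended: bool
    a_tailed: bool = True  # Taq leaves single 3'-A overhangs on the product


def simulate_third_pcr(
    products: list[AssemblyProduct],
    end_fwd_primer: str | DesignedPrimer,
    end_rev_primer: str | DesignedPrimer,
) -> list[ThirdPcrBand]:
    """End-amplification: keep products whose 5' end regenerates the forward
    primer and whose 3' end regenerates the reverse primer; the returned band
    lengths are the predicted ladder, the on-pathway product marked intended."""
    fwd = (end_fwd_primer.sequence if isinstance(end_fwd_primer, DesignedPrimer)
           else check_dna(end_fwd_primer, name="end_fwd_primer"))
    rev = (end_rev_primer.sequence if isinstance(end_rev_primer, DesignedPrimer)
           else check_dna(end_rev_primer, name="end_rev_primer"))
    rev_rc = revcomp(rev)
    bands = [
        ThirdPcrBand(product=p, length=p.length, intended=p.on_pathway)
        for p in products
        if p.seq.startswith(fwd) and p.seq.endswith(rev_rc)
    ]
    return sorted(bands, key=lambda b: -b.length)


# --------------------------------------------------------------------------
# platform vector, digestion, TA cloning, colony PCR
# --------------------------------------------------------------------------


class DigestError(ValueError):
    """Zero or multiple recognition sites where exactly one is required."""


@dataclass(frozen=True)
class PlatformVectorModel:
    """Circular nuclease platform vector.

    The real vector sequence is user-supplied (FASTA/GenBank); a synthetic
    fixture with the same layout ships in :mod:`olta.fixtures`.  ``variant``
    tags the FokI obligate-heterodimer flavour: left arrays go into the KK
    vector, right arrays into the EL vector.
    """

    seq: str  # circular, top strand
    variant: str = "KK"  # "KK" | "EL"
    orf_start: int = 0  # position of the cassette ATG
    features: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", check_dna(self.seq, name="vector seq"))
        if self.variant not in ("KK", "EL"):
            raise ValueError("variant must be 'KK' or 'EL'")

    def find_sites(self, motif: str) -> list[int]:
        """Start positions of ``motif`` on the circular top strand."""
        doubled = self.seq + self.seq[: len(motif) - 1]
        return [
            i for i in range(len(self.seq)) if doubled[i : i + len(motif)] == motif
        ]

    @property
    def t3_position(self) -> Optional[int]:
        hits = self.find_sites(T3_PROMOTER_PRIMER)
        return hits[0] if hits else None


@dataclass(frozen=True)
class LinearizedVector:
    """PvuII/BstZ17I-cut, stuffer-free backbone with 3' ddT overhangs.

    ``seq`` runs from the BstZ17I cut (starts "TAC") around the circle to the
    PvuII cut (ends "CAG"); the insert ligates between those ends.
    """

    seq: str
    variant: str
    orf_start: int  # index of the cassette ATG within seq
    three_prime_t: bool = True


def digest_and_tail(vector: PlatformVectorModel) -> LinearizedVector:
    """Blunt-cut at the unique PvuII (CAG^CTG) and BstZ17I (GTA^TAC) sites,
    drop the stuffer between them, and add a single 3' ddT to both ends."""
    pvu = vector.find_sites(PVUII_SITE)
    bst = vector.find_sites(BSTZ17I_SITE)
    if len(pvu) != 1:
        raise DigestError(f"need exactly one PvuII site, found {len(pvu)} at {pvu}")
    if len(bst) != 1:
        raise DigestError(f"need exactly one BstZ17I site, found {len(bst)} at {bst}")
    L = len(vector.seq)
    pvu_cut = (pvu[0] + 3) % L  # after CAG
    bst_cut = (bst[0] + 3) % L  # after GTA
    doubled = vector.seq + vector.seq
    # backbone = arc from the BstZ17I cut forward to the PvuII cut; the
    # stuffer (PvuII cut -> BstZ17I cut) must not contain the cassette start
    backbone = doubled[bst_cut : bst_cut + (pvu_cut - bst_cut) % L]
    orf = (vector.orf_start - bst_cut) % L
    if orf >= len(backbone):
        raise DigestError("cassette ORF start falls inside the stuffer")
    return LinearizedVector(seq=backbone, variant=vector.variant, orf_start=orf)


@dataclass(frozen=True)
class ClonedConstruct:
    """Circular product of TA ligation (or self-religation)."""

    seq: str  # circular top strand, starting at the backbone's "TAC..."
    orientation: str  # "forward" | "reverse" | "none"
    insert: str
    variant: str
    orf_start: int
    has_insert: bool = True

    def orf_translation(self, max_aa: int = 2000) -> str:
        """Translate the cassette ORF from its ATG, across the circular
        junction, up to (not including) the first stop codon."""
        doubled = self.seq + self.seq
        peptide = []
        for i in range(self.orf_start, self.orf_start + 3 * max_aa, 3):
            codon = doubled[i : i + 3]
            if len(codon) < 3:
                break
            aa = translate(codon)
            if aa == "*":
                break
            peptide.append(aa)
        return "".join(peptide)


def ta_clone(insert: str, backbone: LinearizedVector, a_tailed: bool = True):
    """Ligate an A-tailed insert into the T-tailed backbone.

    Returns the two possible constructs (forward and reverse orientation);
    the single T and A of the junctions become part of the circle.  An insert
    without the A-tail flag still ligates (blunt background) but is warned
    about by callers; an empty insert is an error.
    """
    ins = check_dna(insert, name="insert")
    if not ins:
        raise SequenceError("empty insert cannot be TA-cloned")
    fwd = ClonedConstruct(
        seq=backbone.seq + "T" + ins + "A",
        orientation="forward",
        insert=ins,
        variant=backbone.variant,
        orf_start=backbone.orf_start,
    )
    rev = ClonedConstruct(
        seq=backbone.seq + "T" + revcomp(ins) + "A",
        orientation="reverse",
        insert=ins,
        variant=backbone.variant,
        orf_start=backbone.orf_start,
    )
    return fwd, rev


def self_ligate(backbone: LinearizedVector) -> ClonedConstruct:
    """Insert-less religation product (the 'empty vector' colony)."""
    return ClonedConstruct(
        seq=backbone.seq + "TA",
        orientation="none",
        insert="",
        variant=backbone.variant,
        orf_start=backbone.orf_start,
        has_insert=False,
    )


@dataclass(frozen=True)
class ColonyPcrResult:
    product_length: Optional[int]
    status: str  # "ok" | "wrong_orientation" | "no_insert"


def colony_pcr_check(
    construct: ClonedConstruct,
    t3_primer: str = T3_PROMOTER_PRIMER,
    rev_primer: str | DesignedPrimer = "",
    max_len: int = 2000,
) -> ColonyPcrResult:
    """Virtual colony PCR: T3-promoter primer forward + the 3rd-PCR reverse
    primer.  A product forms only when both primers anneal convergently
    within ``max_len`` -- i.e. the insert is present and in the forward
    orientation; reverse-orientation and empty constructs give no product."""
    rev = (rev_primer.sequence if isinstance(rev_primer, DesignedPrimer)
           else check_dna(rev_primer, name="rev_primer"))
    if not construct.has_insert:
        return ColonyPcrResult(None, "no_insert")
    seq = construct.seq
    doubled = seq + seq
    t3_hits = [i for i in range(len(seq)) if doubled[i : i + len(t3_primer)] == t3_primer]
    if not t3_hits:
        return ColonyPcrResult(None, "no_insert")
    start = t3_hits[0]
    rc = revcomp(rev)
    for off in range(len(seq)):
        pos = (start + off) % len(seq)
        if doubled[pos : pos + len(rc)] == rc:
            length = off + len(rc)
            if length <= max_len:
                return ColonyPcrResult(length, "ok")
            break
    return ColonyPcrResult(None, "wrong_orientation")
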