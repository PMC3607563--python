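"""Synthetic fixture generation for self-contained testing and demos.

Everything here is generated code-side from a seed -- no external data.  The
fixtures emulate (a) the two-helix zinc-finger template reconstructed from
the published cloning primers, (b) a synthetic platform vector with the real
cassette layout (T3 promoter, NLS, PvuII/BstZ17I stuffer, FokI stub, XhoI
site), (c) random genomic sequence with planted paired half-sites, and (d)
mutant reads carrying known substitution/deletion/insertion events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import BSTZ17I_SITE, PVUII_SITE, T3_PROMOTER_PRIMER, XHOI_SITE, PlatformVectorModel
from .genotyping import EditCall
from .registry import HelixRegistry, load_registry
from .scanner import ZfnHalfSite, ZfnSitePair
from .sequences import SequenceError, check_dna, revcomp
from .template import TemplateModel, build_template

BASES = "ACGT"


def make_fixture_template() -> TemplateModel:
    """The two-helix template with the packaged synthetic internal framework
    (104-nt insert whose ends are the published cloning primers).  Repeated
    calls return identical models."""
    return build_template()


# --------------------------------------------------------------------------
# platform vector fixture
# --------------------------------------------------------------------------

_SV40_NLS = "CCAAAAAAGAAGAGAAAGGTC"  # PKKKRKV
_FLAG = "GACTACAAGGACGACGATGACAAG"  # DYKDDDDK epitope tag
# short FokI catalytic-domain stub (enough ORF to check frame), then stop
_FOKI_STUB = (
    "CAACTAGTGAAAAGTGAACTGGAGGAGAAGAAATCTGAACTTCGTCATAAATTGAAATATGTG"  # QLVKSELEEKKSELRHKLKYV
)

_FORBIDDEN = (PVUII_SITE, BSTZ17I_SITE, XHOI_SITE, T3_PROMOTER_PRIMER)


def _random_dna(rng: np.random.Generator, n: int, forbidden=_FORBIDDEN) -> str:
    """Random sequence free of the fixture's restriction/priming motifs."""
    while True:
        seq = "".join(rng.choice(list(BASES), size=n))
        if not any(m in seq for m in forbidden):
            return seq


def make_fixture_vector(variant: str = "KK", seed: int = 0) -> PlatformVectorModel:
    """Synthetic circular platform vector.

    Layout (top strand): filler | T3 promoter | 5' UTR | ATG-FLAG-NLS ORF
    head ending in the PvuII half-site CAG | stuffer | BstZ17I half-site TAC
    leading in-frame into the FokI stub | stop | XhoI site | filler.  The
    frame is arranged so that TA-cloning an OLTA 3rd-PCR product between the
    CAG^T and A^TAC junctions yields NLS - ZF array - FokI in one ORF.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    utr = _random_dna(rng, 12)
    # ORF head: ATG + FLAG + NLS + GC pad so that (head + "CAGT") % 3 == 0
    head = "ATG" + _FLAG + _SV40_NLS
    head += _random_dna(rng, (-len(head) - 4 - 2) % 3 + 2)  # pad to len % 3 == 2
    assert (len(head) + 4) % 3 == 0
    stuffer = _random_dna(rng, 120)
    # after "...A TAC" the next codon is (C, x0, x1): lead the FokI stub with
    # "C" so the junction reads ...C A T | A C C | stub in frame
    downstream = "C" + _FOKI_STUB + "TAA"
    vector_seq = (
        _random_dna(rng, 40)
        + T3_PROMOTER_PRIMER
        + utr
        + head
        + PVUII_SITE  # CAG^CTG: the CAG completes the ORF head
        + stuffer
        + BSTZ17I_SITE  # GTA^TAC
        + downstream
        + XHOI_SITE
        + _random_dna(rng, 60)
    )
    orf_start = 40 + len(T3_PROMOTER_PRIMER) + len(utr)
    vec = PlatformVectorModel(
        seq=vector_seq,
        variant=variant,
        orf_start=orf_start,
        features={
            "t3_promoter": (40, 40 + len(T3_PROMOTER_PRIMER)),
            "orf_start": orf_start,
            "xhoi": vector_seq.index(XHOI_SITE),
        },
    )
    if len(vec.find_sites(PVUII_SITE)) != 1 or len(vec.find_sites(BSTZ17I_SITE)) != 1:
        raise AssertionError("fixture vector must carry unique cloning sites")
    return vec


# --------------------------------------------------------------------------
# planted genomes
# --------------------------------------------------------------------------


@dataclass
class FixtureSpec:
    seed: int = 1
    genome_length: int = 1000
    n_planted_sites: int = 1
    finger_range: tuple[int, int] = (4, 6)
    spacer_range: tuple[int, int] = (5, 6)
    registry: HelixRegistry = field(default_factory=load_registry)


@dataclass(frozen=True)
class PlantedSite:
    """Truth record for one planted pair (plus-strand coordinates)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_site: str  # 5'->3' on the minus strand
    right_site: str  # 5'->3' on the plus strand
    spacer_seq: str

    def as_pair(self) -> ZfnSitePair:
        return ZfnSitePair(
            left=ZfnHalfSite("-", self.left_start, self.left_end, self.left_site),
            right=ZfnHalfSite("+", self.right_start, self.right_end, self.right_site),
            spacer_seq=self.spacer_seq,
        )

    def bed_line(self, chrom: str = "fixture") -> str:
        return "\t".join(
            str(x)
            for x in (
                chrom,
                self.left_start,
                self.right_end,
                f"{self.left_site}/{self.right_site}",
                len(self.spacer_seq),
            )
        )


def make_planted_genome(spec: FixtureSpec) -> tuple[str, list[PlantedSite]]:
    """Random genome with ``n_planted_sites`` non-overlapping planted pairs.

    Each pair is revcomp(left site) + spacer + right site with half-sites
    built from random registry triplets.  Deterministic per seed.  Raises if
    the requested sites cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    triplets = spec.registry.triplets()
    genome = list("".join(rng.choice(list(BASES), size=spec.genome_length)))
    truth: list[PlantedSite] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(spec.n_planted_sites):
        n_left = int(rng.integers(spec.finger_range[0], spec.finger_range[1] + 1))
        n_right = int(rng.integers(spec.finger_range[0], spec.finger_range[1] + 1))
        spacer_len = int(rng.integers(spec.spacer_range[0], spec.spacer_range[1] + 1))
        left_site = "".join(rng.choice(triplets) for _ in range(n_left))
        right_site = "".join(rng.choice(triplets) for _ in range(n_right))
        spacer = "".join(rng.choice(list(BASES), size=spacer_len))
        block = revcomp(left_site) + spacer + right_site
        placed = False
        for _attempt in range(200):
            pos = int(rng.integers(0, spec.genome_length - len(block) + 1))
            if all(pos + len(block) <= s or pos >= e for s, e in occupied):
                placed = True
                break
        if not placed:
            raise SequenceError(
                f"could not place {spec.n_planted_sites} non-overlapping sites "
                f"in {spec.genome_length} nt"
            )
        occupied.append((pos, pos + len(block)))
        genome[pos : pos + len(block)] = list(block)
        left_end = pos + 3 * n_left
        truth.append(
            PlantedSite(
                left_start=pos,
                left_end=left_end,
                right_start=left_end + spacer_len,
                right_end=left_end + spacer_len + 3 * n_right,
                left_site=left_site,
                right_site=right_site,
                spacer_seq=spacer,
            )
        )
    return "".join(genome), sorted(truth, key=lambda t: t.left_start)


# --------------------------------------------------------------------------
# mutant reads
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EditSpec:
    """One read's worth of contiguous edit events.

    Each nonzero category is applied as a single contiguous event at its
    position (substitution run at ``sub_pos``, deletion at ``del_pos``,
    insertion at ``ins_pos``), mirroring clean NHEJ outcomes.
    """

    n_sub: int = 0
    n_del: int = 0
    n_ins: int = 0
    sub_pos: int = 0
    del_pos: int = 0
    ins_pos: int = 0


_SUB_ROTATION = {"A": "C", "C": "G", "G": "T", "T": "A"}


def make_mutant_reads(
    wt: str, edit_specs: list[EditSpec], seed: int = 1
) -> list[tuple[str, EditCall]]:
    """Apply each edit spec to the wild type; returns (read, truth call).

    Substitutions rotate the base (A->C->G->T->A) so they always differ from
    the wild type; inserted bases are drawn from the seeded generator.
    Events are applied right-to-left so positions refer to wild-type
    coordinates; out-of-bounds events raise.
    """
    wt = check_dna(wt, name="wt")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, EditCall]] = []
    for spec in edit_specs:
        events = []  # (pos, kind, n); applied right-to-left
        if spec.n_sub:
            events.append((spec.sub_pos, "S", spec.n_sub))
        if spec.n_del:
            events.append((spec.del_pos, "D", spec.n_del))
        if spec.n_ins:
            events.append((spec.ins_pos, "I", spec.n_ins))
        for pos, kind, n in events:
            end = pos + (n if kind in "SD" else 0)
            if pos < 0 or end > len(wt):
                raise SequenceError(f"edit {kind}x{n} at {pos} outside wild type")
        read = wt
        for pos, kind, n in sorted(events, reverse=True):
            if kind == "S":
                run = "".join(_SUB_ROTATION[b] for b in read[pos : pos + n])
                read = read[:pos] + run + read[pos + n :]
            elif kind == "D":
                read = read[:pos] + read[pos + n :]
            else:
                ins = "".join(rng.choice(list(BASES), size=n))
                read = read[:pos] + ins + read[pos:]
        out.append((read, EditCall(spec.n_sub, spec.n_del, spec.n_ins)))
    return out
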