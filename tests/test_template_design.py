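"""Template reconstruction and mismatch-minimizing primer design.

The independent oracle for the designer is exhaustive enumeration of every
synonymous codon combination for a helix (itertools.product over the codon
table), scored by Hamming distance against the slot reference.
"""

import itertools
import random

import pytest

from olta import (
    DesignError,
    build_template,
    check_three_prime_anchor,
    count_mismatches,
    design_array_primer_pair,
    design_forward_primer,
    design_reverse_primer,
    design_shared_codons,
)
from olta.sequences import AA_TO_CODONS, SequenceError, revcomp


def brute_force_min_mismatches(helix: str, codon_ref: str) -> int:
    """Minimum Hamming distance over all synonymous encodings of ``helix``."""
    best = len(codon_ref) + 1
    for combo in itertools.product(*(AA_TO_CODONS[aa] for aa in helix)):
        dist = sum(a != b for a, b in zip("".join(combo), codon_ref))
        best = min(best, dist)
    return best


# -- template model ---------------------------------------------------------


def test_template_reconstruction(template):
    assert template.rev_ref == "GGCGGGCAAGATTATCCGAGCGACTGAAG"
    assert template.helix1 == "RSDALTR"
    assert template.helix2 == "RSDNLAR"
    assert template.fwd_ref.endswith("CATATCCG")
    assert template.rev_ref[-7:] == "ACTGAAG"
    assert template.total_length == 104
    assert template.insert_seq.startswith(template.fwd_ref)
    # 3' end of the insert is the reverse complement of the 27-nt cloning primer
    assert template.insert_seq.endswith(revcomp(template.rev_ref[2:]))


def test_build_template_validates_lengths():
    with pytest.raises(SequenceError):
        build_template(fwd_cloning_primer="CGCTCGGATGCGCTTACCCGCCATATCC")  # 28 nt
    with pytest.raises(SequenceError):
        build_template(rev_cloning_primer="CGGGCAAGATTATCCGAGCGACTGAAGA")  # 28 nt


def test_count_mismatches(template, registry):
    assert count_mismatches("ACGT", "ACGT") == 0
    assert count_mismatches(registry.lookup("GAG").fwd_primer, template.fwd_ref) == 4
    assert count_mismatches(registry.lookup("CTG").rev_primer, template.rev_ref) == 11
    with pytest.raises(SequenceError):
        count_mismatches("ACG", "ACGT")


def test_three_prime_anchor(template, registry):
    for entry in registry:
        assert check_three_prime_anchor(entry.fwd_primer, template.fwd_ref, k=8)
        assert check_three_prime_anchor(entry.rev_primer, template.rev_ref, k=7)
    gat = registry.lookup("GAT")
    assert not check_three_prime_anchor(gat.rev_primer, template.rev_ref, k=9)
    assert check_three_prime_anchor(template.fwd_ref, template.fwd_ref, k=29)


# -- designers --------------------------------------------------------------


def test_designed_counts_for_template_helices(template):
    # frozen from the brute-force oracle
    assert design_forward_primer("RSDALTR", template).ndn == 0
    assert design_forward_primer("RSDNLAR", template).ndn == 4
    assert design_reverse_primer("RSDNLAR", template).ndn == 0
    assert design_reverse_primer("RSDALTR", template).ndn == 3


def test_designed_primer_structure(template):
    pair = design_array_primer_pair("QSGDLTR", template)
    assert pair.fwd_primer == pair.fwd.codons + "CATATCCG"
    assert pair.rev_primer == revcomp("CTTCAGT" + pair.rev.codons + "C")
    assert pair.fwd.anchor_ok and pair.rev.anchor_ok
    assert count_mismatches(pair.fwd_primer, template.fwd_ref) == pair.fwd_ndn
    assert count_mismatches(pair.rev_primer, template.rev_ref) == pair.rev_ndn


def test_invalid_helix_rejected(template):
    with pytest.raises(SequenceError):
        design_forward_primer("XXXXXXX", template)
    with pytest.raises(SequenceError):
        design_reverse_primer("RSDALT", template)  # 6 residues


def test_mismatch_cap_violation_carries_best_design(template):
    with pytest.raises(DesignError) as err:
        design_forward_primer("WWWWWWW", template, max_mismatch=3)
    best = err.value.best
    assert best.ndn > 3
    assert count_mismatches(best.sequence, template.fwd_ref) == best.ndn


@pytest.mark.parametrize("direction", ["fwd", "rev"])
def test_designer_matches_brute_force_on_registry_helices(registry, template, direction):
    """The per-residue greedy choice equals exhaustive enumeration."""
    for entry in registry:
        ref = template.fwd_codon_ref if direction == "fwd" else template.rev_codon_ref
        designer = design_forward_primer if direction == "fwd" else design_reverse_primer
        assert designer(entry.helix, template).ndn == brute_force_min_mismatches(
            entry.helix, ref
        )


def test_designer_matches_brute_force_on_random_helices(template):
    rng = random.Random(20130325)
    aas = sorted(AA_TO_CODONS)
    for _ in range(10):
        helix = "".join(rng.choice(aas) for _ in range(7))
        assert (
            design_forward_primer(helix, template, max_mismatch=21).ndn
            == brute_force_min_mismatches(helix, template.fwd_codon_ref)
        )
        assert (
            design_reverse_primer(helix, template, max_mismatch=21).ndn
            == brute_force_min_mismatches(helix, template.rev_codon_ref)
        )


def test_designer_never_beaten_by_published_primers(registry, template):
    """The published primers are feasible points: the optimizer's count is
    never larger than the published primer's actual distance to the
    template."""
    for entry in registry:
        assert (
            design_forward_primer(entry.helix, template).ndn
            <= count_mismatches(entry.fwd_primer, template.fwd_ref)
        )
        assert (
            design_reverse_primer(entry.helix, template).ndn
            <= count_mismatches(entry.rev_primer, template.rev_ref)
        )


def test_shared_codons_reproduce_template_slots(template):
    """Encoding the template's own helices with the shared-codon designer
    reproduces each slot exactly (so identity fragments equal the template)."""
    codons1, fwd1, _ = design_shared_codons("RSDALTR", template)
    assert codons1 == template.fwd_codon_ref and fwd1 == 0
    codons2, _, rev2 = design_shared_codons("RSDNLAR", template)
    assert codons2 == template.rev_codon_ref and rev2 == 0


def test_shared_codons_identical_across_directions(template, registry):
    """One codon assignment serves both primer directions, and its summed
    cost is optimal by the same exhaustive oracle."""
    for entry in list(registry)[:5]:
        codons, fwd_ndn, rev_ndn = design_shared_codons(entry.helix, template)
        pair = design_array_primer_pair(entry.helix, template)
        assert pair.fwd.codons == pair.rev.codons == codons
        best_sum = min(
            sum(a != b for a, b in zip("".join(c), template.fwd_codon_ref))
            + sum(a != b for a, b in zip("".join(c), template.rev_codon_ref))
            for c in itertools.product(*(AA_TO_CODONS[aa] for aa in entry.helix))
        )
        assert fwd_ndn + rev_ndn == best_sum
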