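"""Reaction planning, overlap-extension assembly, TA cloning, colony PCR."""

import pytest

from olta import (
    PlanError,
    assembly_is_ambiguous,
    colony_pcr_check,
    digest_and_tail,
    make_fixture_vector,
    plan_reactions,
    self_ligate,
    simulate_overlap_assembly,
    simulate_third_pcr,
    synthesize_fragment,
    synthesize_fragments,
    ta_clone,
)
from olta.assembly import BSTZ17I_SITE, PVUII_SITE, DigestError, PlatformVectorModel
from olta.sequences import SequenceError, revcomp, translate
from conftest import PUBLISHED_ARRAYS


@pytest.fixture(scope="module")
def gli3_fragments(registry, template):
    helices = [registry.lookup(t).helix for t in PUBLISHED_ARRAYS["Gli3_left"]]
    return synthesize_fragments(template, helices)


# -- planning ---------------------------------------------------------------


def test_gli3_left_plan(registry):
    plan = plan_reactions(["GCC", "TGG", "CTG", "GAG"], registry)
    assert plan.first_pcr == (("GCC", "TGG"), ("TGG", "CTG"), ("CTG", "GAG"))
    assert plan.third_pcr == ("GCC", "GAG")
    assert plan.n_fragments == 3


@pytest.mark.parametrize(
    "key,n",
    [("Gli3_left", 4), ("Il2rg_left", 5), ("Rosa26_left", 6)],
)
def test_fragment_count_is_fingers_minus_one(registry, key, n):
    plan = plan_reactions(PUBLISHED_ARRAYS[key], registry)
    assert plan.n_fingers == n
    assert plan.n_fragments == n - 1
    # end fragments at 0.5 ul, exactly one middle fragment at 1.5 ul for the
    # 4- and 6-finger recipes, two for the 5-finger recipe
    volumes = sorted(plan.second_pcr_mix_ul.values())
    assert volumes.count(1.5) == (2 if n == 5 else 1)


def test_plan_rejects_out_of_range_and_unknown(registry):
    with pytest.raises(PlanError):
        plan_reactions(["GCC", "TGG"], registry)
    with pytest.raises(KeyError):
        plan_reactions(["GCC", "TGG", "CTG", "AAA"], registry)


# -- fragments --------------------------------------------------------------


def test_identity_fragment_reproduces_template(template):
    """The template's own helices yield a fragment whose ends are exactly the
    template's annealing references."""
    frag = synthesize_fragment(template, "RSDALTR", "RSDNLAR")
    assert frag.seq.startswith(template.fwd_ref)
    assert frag.seq.endswith(revcomp(template.rev_ref))
    assert frag.seq == template.amplicon_seq


def test_fragment_lengths_equal_for_any_helix_pair(template):
    f1 = synthesize_fragment(template, "QSGDLTR", "TSGSLVR")
    f2 = synthesize_fragment(template, "RKDNLKN", "QLAHLRA")
    assert f1.length == f2.length == template.total_length + 2
    assert translate(f1.seq[:21]) == "QSGDLTR"
    assert translate(f1.seq[-22:-1]) == "TSGSLVR"


# -- overlap assembly -------------------------------------------------------


def test_distinct_helices_give_unique_on_pathway_chain(gli3_fragments):
    products = simulate_overlap_assembly(gli3_fragments)
    assert len(products) == 1
    assert products[0].on_pathway
    assert products[0].chain == (0, 1, 2)


def test_assembled_orf_carries_helices_in_order(registry, template, gli3_fragments):
    (product,) = simulate_overlap_assembly(gli3_fragments)
    helices = [registry.lookup(t).helix for t in PUBLISHED_ARRAYS["Gli3_left"]]
    assert list(product.helix_order) == helices
    # the repeating unit is 84 nt (28 codons); helices sit at its start
    for k, helix in enumerate(helices):
        assert translate(product.seq[84 * k : 84 * k + 21]) == helix


def test_repeated_helix_creates_ambiguity(template):
    frags = synthesize_fragments(template, ["QSGDLTR", "TSGSLVR", "QSGDLTR", "RSDHLSR"])
    products = simulate_overlap_assembly(frags)
    assert assembly_is_ambiguous(products)
    assert any(not p.on_pathway for p in products)
    assert any(p.on_pathway for p in products)


def test_single_fragment_passthrough(template):
    frag = synthesize_fragment(template, "QSGDLTR", "TSGSLVR")
    products = simulate_overlap_assembly([frag])
    assert len(products) == 1 and products[0].seq == frag.seq


def test_band_length_monotonicity(registry, template):
    helices = [registry.lookup(t).helix for t in PUBLISHED_ARRAYS["Rosa26_left"]]
    frags = synthesize_fragments(template, helices)
    products = simulate_overlap_assembly(frags, maximal_only=False)
    by_n = {}
    for p in products:
        by_n.setdefault(p.n_fragments, set()).add(p.length)
    lengths = [max(by_n[n]) for n in sorted(by_n)]
    assert lengths == sorted(set(lengths))  # strictly longer with more fragments


def test_third_pcr_keeps_full_chain_and_marks_intended(gli3_fragments):
    products = simulate_overlap_assembly(gli3_fragments, maximal_only=False)
    bands = simulate_third_pcr(
        products, gli3_fragments[0].fwd_primer, gli3_fragments[-1].rev_primer
    )
    assert len(bands) == 1
    assert bands[0].intended and bands[0].a_tailed
    assert bands[0].length == 84 * 3 + 22


def test_third_pcr_ladder_for_ambiguous_assembly(template):
    frags = synthesize_fragments(template, ["QSGDLTR", "TSGSLVR", "QSGDLTR", "RSDHLSR"])
    products = simulate_overlap_assembly(frags, maximal_only=False)
    bands = simulate_third_pcr(products, frags[0].fwd_primer, frags[-1].rev_primer)
    assert len(bands) > 1  # the published gels show ladders
    assert sum(b.intended for b in bands) == 1


def test_third_pcr_with_foreign_primers_is_empty(gli3_fragments, registry, template):
    products = simulate_overlap_assembly(gli3_fragments)
    from olta import design_array_primer_pair

    foreign = design_array_primer_pair("QSGNLAR", template)
    assert simulate_third_pcr(products, foreign.fwd.sequence, foreign.rev.sequence) == []


# -- vector, cloning, colony PCR -------------------------------------------


@pytest.fixture(scope="module")
def construct_pair(gli3_fragments):
    vector = make_fixture_vector()
    backbone = digest_and_tail(vector)
    (product,) = simulate_overlap_assembly(gli3_fragments)
    fwd, rev = ta_clone(product.seq, backbone)
    return backbone, fwd, rev


def test_digest_requires_unique_sites():
    vector = make_fixture_vector()
    assert len(vector.find_sites(PVUII_SITE)) == 1
    assert len(vector.find_sites(BSTZ17I_SITE)) == 1
    broken = PlatformVectorModel(
        seq=vector.seq.replace(PVUII_SITE, "CAGGTG", 1), orf_start=vector.orf_start
    )
    with pytest.raises(DigestError):
        digest_and_tail(broken)


def test_digest_drops_stuffer_and_tails(construct_pair):
    backbone, _, _ = construct_pair
    vector = make_fixture_vector()
    assert backbone.three_prime_t
    assert backbone.seq.startswith("TAC") and backbone.seq.endswith("CAG")
    assert len(backbone.seq) < len(vector.seq)
    # idempotence: the cut backbone has no remaining recognition sites
    assert PVUII_SITE not in backbone.seq and BSTZ17I_SITE not in backbone.seq


def test_ta_clone_returns_both_orientations(construct_pair):
    backbone, fwd, rev = construct_pair
    assert fwd.seq != rev.seq
    assert fwd.seq == backbone.seq + "T" + fwd.insert + "A"
    assert rev.seq == backbone.seq + "T" + revcomp(fwd.insert) + "A"
    with pytest.raises(SequenceError):
        ta_clone("", backbone)


def test_forward_construct_orf_in_frame(construct_pair, registry):
    """NLS - ZF array - FokI reads as one frame on the forward construct."""
    _, fwd, _ = construct_pair
    orf = fwd.orf_translation()
    assert "PKKKRKV" in orf  # SV40 NLS
    helices = [registry.lookup(t).helix for t in PUBLISHED_ARRAYS["Gli3_left"]]
    assert all(h in orf for h in helices)
    assert orf.index("PKKKRKV") < orf.index(helices[0]) < orf.index("QLVKSELEEKK")


def test_colony_pcr_screens_orientation(construct_pair, gli3_fragments):
    backbone, fwd, rev = construct_pair
    rp = gli3_fragments[-1].rev_primer
    ok = colony_pcr_check(fwd, rev_primer=rp)
    assert ok.status == "ok" and ok.product_length is not None
    assert colony_pcr_check(rev, rev_primer=rp).status == "wrong_orientation"
    assert colony_pcr_check(self_ligate(backbone), rev_primer=rp).status == "no_insert"
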