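"""Shared fixtures: the packaged registry, the reconstructed template, and
the published target loci / genotype rows used across the suite."""

import pytest

from olta import build_template, load_registry

# wild-type target-locus amplicons (sequenced regions around each ZFN site)
WT_AMPLICONS = {
    "Gli3": "AGGCCCACAGCTCTACGGCGACTGAGAGGAAG",
    "Rosa26": "CTGCAACTCCAGTCTTTCTAGAAGATGGGCGGGAGTCT",
    "Il2rg": "ACCAACCTCACGCTGCACTATAGGTATGAGAAGGGGGA",
    "Cdkn1b": "GGTCCACACCCGCCCGAGGAGGAAGATGTCA",
}

# published half-site pairs: (left site 5'->3' on minus strand, right site on
# plus strand, spacer length); finger arrays are the triplets in ZF order
PUBLISHED_PAIRS = {
    "Gli3": ("GAGCTGTGGGCC", "GACTGAGAGGAA", 6),
    "Rosa26": ("AGAAAGACTGGAGTTGCA", "TGGGCGGGAGTC", 6),
    "Il2rg": ("GCAGCGTGAGGTTGG", "GGTATGAGAAGGGGG", 6),
    "Cdkn1b": ("GCGGGTGTGGAC", "GAGGAAGATGTC", 5),
}

PUBLISHED_ARRAYS = {
    "Gli3_left": ["GCC", "TGG", "CTG", "GAG"],
    "Gli3_right": ["GAA", "GAG", "TGA", "GAC"],
    "Rosa26_left": ["GCA", "GTT", "GGA", "ACT", "AAG", "AGA"],
    "Rosa26_right": ["GTC", "GGA", "GCG", "TGG"],
    "Il2rg_left": ["TGG", "GGT", "TGA", "GCG", "GCA"],
    "Il2rg_right": ["GGG", "AGG", "AGA", "ATG", "GGT"],
    "Cdkn1b_left": ["GAC", "GTG", "GGT", "GCG"],
    "Cdkn1b_right": ["GTC", "GAT", "GAA", "GAG"],
}

# published mutant reads with an unambiguous edit annotation (wt key, read,
# expected label); rows mixing unannotated changes are excluded
CLEAN_MUTANT_ROWS = [
    ("Cdkn1b", "GGTCCACACCCACCGGAGGAGGAAGATGTCA", "2 S"),
    ("Cdkn1b", "GGTCCACACCCGCCCAGGAGGAAGATGTCA", "1 D"),
    ("Cdkn1b", "GGTCCACACCCGCCAGGAGGAAGATGTCA", "2 D"),
    ("Gli3", "AGGCCCACAGCTCTCGGCGACTGAGAGGAAG", "1 D"),
    ("Gli3", "AGGCCCACAGTTTTGCGACTGAGAGGAAG", "3 D, 2 S"),
    ("Rosa26", "CTGCAACTCCAGTCTTTCTAGATGGGCGGGAGTCT", "3 D"),
    ("Rosa26", "CTGCAACTCCAGTCTTTCTAGAATGGGCGGGAGTCT", "2 D"),
    ("Rosa26", "CTGCAACTCCAGTCTTTCTAGAAGGGCGGGAGTCT", "3 D"),
    ("Rosa26", "CTGCAACTCCAGTCTTTATGGGCGGGAGTCT", "7 D"),
    ("Rosa26", "CTGCAACTCCAGTCTTTCTATGGGCGGGAGTCT", "5 D"),
    ("Il2rg", "ACCAACCTCACGCTGCACAGGTATGAGAAGGGGGA", "3 D"),
    ("Il2rg", "ACCAACCTCACGCTGCACGGTATGAGAAGGGGGA", "4 D"),
    ("Il2rg", "ACCAACCTCACGCTGCATGAGAAGGGGGA", "9 D"),
    ("Il2rg", "ACCAACCTCACGCTGGGTATGAGAAGGGGGA", "7 D"),
]

# newborn-genotype amplicon for the Gli3 locus is 5 nt longer at the 3' end
WT_GLI3_LONG = "AGGCCCACAGCTCTACGGCGACTGAGAGGAAGAAAGC"
CLEAN_MUTANT_ROWS_LONG = [
    (WT_GLI3_LONG, "AGGCCCACAGCTCTCGGCGACTGAGAGGAAGAAAGC", "1 D"),
    (WT_GLI3_LONG, "AGGCCCACAGCTCTAGGCGACTGAGAGGAAGAAAGC", "1 D"),
    (WT_GLI3_LONG, "AGGCCCACAGCTCTAGCGACTGAGAGGAAGAAAGC", "2 D"),
    (WT_GLI3_LONG, "AGGCCCACAGCTCTGACTGAGAGGAAGAAAGC", "5 D"),
    (WT_GLI3_LONG, "AGGCCCACAGCTCTACGGGGCGACTGAGAGGAAGAAAGC", "2 I"),
]


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def template():
    return build_template()
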