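# olta

In-silico design, assembly simulation and genotyping for zinc-finger
nucleases (ZFNs) built by **O**ver**L**ap-extension PCR and **TA** cloning
(OLTA).

## Who this is for

ZFNs are chimeric nucleases: 4–6 C2H2 zinc fingers, each binding one DNA
triplet through a 7-amino-acid recognition helix, fused to the FokI cleavage
domain.  A ZFN pair binds two half-sites on opposite strands with a 5–6 bp
spacer and cuts between them; error-prone repair then leaves substitutions,
deletions and insertions at the target.  The OLTA construction method makes
a new ZFN from a single two-helix template and one reusable 29-nt primer
pair per triplet: n−1 first-PCR fragments, primer-free overlap extension
through the shared helix codons, end amplification, and TA cloning into a
nuclease platform vector.

This package is for people planning or debugging such constructions in
silico: finding candidate paired half-sites in a locus, back-translating
helices onto minimal-mismatch primers, predicting assembly products,
ladders and misassembly risks before touching a thermocycler, and calling
edits in sequenced amplicons afterwards.

## The core computations

* **Primer design.**  For helix residues $a_1..a_7$ and template codons
  $r_1..r_7$, the designer picks
  $c_i = \arg\min_{c \in \mathrm{syn}(a_i)} d_H(c, r_i)$ per residue; the
  summed Hamming distance is the exact global minimum over all synonymous
  encodings (residues are independent).  Constraints: ≤ 11 mismatches to
  the template per primer and a perfectly complementary 3′ end (8 nt
  forward, 7 nt reverse).  Fragment synthesis uses a shared codon
  assignment per helix (minimizing the summed distance to both template
  slots) so the designed 21-nt overlaps between adjacent fragments are
  exact.
* **Site scanning.**  A pair is $\mathrm{rc}(L)\,\cdot\,s\,\cdot\,R$ on the
  plus strand with $|s| \in [5,6]$ and every triplet of $L$ and $R$ in the
  21-entry helix registry; ZF1 binds the 3′-most triplet of its half-site.
* **Assembly.**  Fragments are nodes, exact suffix–prefix overlaps ≥ 21 nt
  are edges; maximal simple paths are the overlap-extension products, with
  on-pathway/ambiguity flags and predicted 3rd-PCR band ladders.
* **Genotyping.**  Global affine alignment (match +1, mismatch −1, gap open
  −4, extend −0.5) against the wild-type amplicon; aligned columns tally
  into calls such as `3 D, 2 S`, plus a T7 endonuclease I fragment-size
  prediction.

See `docs/methods.md` for the full model and its assumptions.

## Worked example

Scan a wild-type amplicon of the mouse *Cdkn1b* locus for paired half-sites:

```
$ olta scan cdkn1b_wt.fasta
# cdkn1b_wt: 1 pair(s)
    chrom  start  end    left_site   right_site fingers  spacer
cdkn1b_wt      1   30 GCGGGTGTGGAC GAGGAAGATGTC     4+4       5
```

One 4+4-finger pair: the left half-site `GCGGGTGTGGAC` (read on the minus
strand, its reverse complement occupying positions 1–13), a 5-bp spacer,
and the right half-site `GAGGAAGATGTC` on the plus strand — so the left
array needs fingers for GAC·GTG·GGT·GCG (ZF1 first) and the right for
GTC·GAT·GAA·GAG.

Design primers for two registry helices:

```
$ olta design GAG GTG
  helix                    fwd_primer  fwd_ndn  ...                    rev_primer  rev_ndn
RSDNLAR CGCTCGGATAACCTTGCCCGCCATATCCG        4  ... GGCGGGCAAGATTATCCGAGCGACTGAAG        0
RSDALTR CGCTCGGATGCGCTTACCCGCCATATCCG        0  ... GGCGGGTAAGAGCATCCGAGCGACTGAAG        3
```

`fwd_ndn`/`rev_ndn` count nucleotide differences to the two-helix template:
the GTG helix (RSDALTR) is the template's own first helix, so its forward
primer needs 0 changes; the GAG helix (RSDNLAR) is the template's second
helix, so its reverse primer needs 0 and its forward primer 4.

Genotype three reads against the same amplicon:

```
$ olta genotype wt.fasta reads.txt
 read  n_sub  n_del  n_ins label
read1      0      0      0    WT
read2      0      1      0   1 D
read3      2      0      0   2 S
examined 3, mutated 2
```

`plan`, `assemble` and `clone` cover the rest of the workflow (reaction
sheets, band ladders, virtual TA cloning and the colony-PCR orientation
screen); `olta fixtures` writes seeded synthetic genomes with planted sites
for testing.

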