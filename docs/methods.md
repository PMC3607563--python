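# Methods

## The workflow being modeled

A zinc-finger nuclease (ZFN) is a fusion of 4–6 C2H2 zinc fingers with the
FokI nuclease domain.  Each finger binds one DNA triplet through a
7-amino-acid recognition helix; a ZFN pair binds two half-sites on opposite
strands of the target locus, separated by a 5–6 bp spacer where the FokI
domains dimerize and cut.  The OLTA construction method (OverLap-extension
PCR and TA cloning) builds the DNA-binding domain from a single two-helix
template using one reusable primer pair per triplet:

1. **1st PCR** — for an n-finger array, n−1 reactions on the two-helix
   template, each with the forward primer of finger *i* and the reverse
   primer of finger *i+1*, produce "partial" fragments spanning one helix to
   the next.
2. **2nd PCR** — primer-free overlap extension joins fragments through their
   shared helix-coding ends.
3. **3rd PCR** — end primers (ZF1 forward, ZFn reverse) amplify the
   full-length chain; gels show a ladder with one band at the intended size.
4. **TA cloning** — the A-tailed product ligates into a PvuII/BstZ17I-cut,
   3′-ddT-tailed platform vector carrying the T3 promoter, an NLS, the FokI
   domain (KK variant for left arrays, EL for right) and an XhoI
   linearization site; colony PCR with the T3-promoter primer and the
   3rd-PCR reverse primer screens insert presence and orientation.

The package simulates each step at nucleotide level and adds the two flanking
analyses: target-site discovery and genotype classification of edited reads.

## Template model

The template spans the region from the first to the second recognition helix
of a natural two-finger unit.  It is reconstructed from its two cloning
primers:

* `fwd_ref` (29 nt) — the forward cloning primer: 21 helix-1 codons
  (`RSDALTR`) plus the constant 8-nt tail `CATATCCG`.
* `rev_ref` (29 nt) — `"GG"` + the 27-nt reverse cloning primer, written on
  the primer strand.  The two extra nucleotides are the genomic context just
  beyond the cloned insert; the convention is pinned by the catalog's GAG
  reverse primer, which equals exactly this 29-mer with zero recorded
  mismatches.  Mapped to the top strand, `revcomp(rev_ref)` reads: 7 nt of
  constant framework, 21 helix-2 codons (`RSDNLAR`), 1 framework nt.  All
  reverse-primer mismatch positions therefore fall in primer positions
  [1, 22); positions 0 and [22, 29) (the 7-nt 3′ anchor `ACTGAAG`) are
  constant.

The 48 nt between the two annealing regions are not part of the printed
primer data; the shipped default (`SYNTHETIC_INTERNAL_FRAMEWORK`) is a
clearly-labelled **synthetic** stand-in that encodes the canonical C2H2
inter-helix framework peptide `HIRIHTGQKPFQCRICMRNFS` with fixed, arbitrary
codons, pinned at both ends by the cloning primers.  It brings the insert to
104 nt and keeps every helix in frame at an 84-nt (28-codon) period.  Users
with the real template supply it as FASTA; none of the mismatch counts
depend on the framework choice.

First-PCR amplicons are 106 nt — the 104-nt insert plus the reverse primer's
2-nt 5′ extension — and all have identical length regardless of the helices
substituted.

## Primer design

A helix is back-translated onto the template by choosing, per residue, the
synonymous codon with the fewest nucleotide differences to the template
codon.  Residues contribute independently, so the per-residue greedy choice
is the exact optimum over all synonymous combinations (the test suite checks
this against exhaustive enumeration).  Ties go to the lexicographically
smallest codon — deterministic and seed-free.  Constraints: at most
`max_mismatch = 11` differences per primer, and exact 3′ ends (8 nt on
forward primers, 7 nt on reverse primers; the catalog itself guarantees only
7 on the reverse side, so both are configurable).

Because the template's two helix slots differ at residues 4 and 6,
direction-wise optimal designs can pick different codons for the same helix,
which would break the exact overlaps between adjacent fragments.  Fragment
synthesis therefore uses a **shared-codon** design that minimizes the summed
distance to both slot references; encoding the template's own helices this
way reproduces each slot exactly.  Notably, 4 of the 21 catalog primer pairs
encode a 1-nt codon disagreement between their own forward and reverse
primers (annealing tolerates it at the bench; an exact-match simulation
cannot), which is why the simulator designs its own primers rather than
reusing the catalog sequences.

The catalog's recorded mismatch counts ("NDN", number of different
nucleotides versus the template vector) are transcribed verbatim.
`validate_registry` recomputes all 42 and reports per-entry agreement
instead of raising: five recorded values are internally inconsistent with
their own primer sequences (three are provably below the achievable minimum
over synonymous codons), and the recomputed values are the arithmetically
correct ones.  37/42 agree.

## Target-site scanner

Coordinates are 0-based half-open on the input plus strand.  A pair is
`revcomp(left site) · spacer · right site` with the left half-site read
5′→3′ on the minus strand; ZF1 (the N-terminal finger) binds the 3′-most
triplet of its half-site, so finger order is the reverse of reading order.
Defaults: 4–6 fingers per side (asymmetric pairs allowed), spacer 5–6 bp,
every triplet must be in the registry.  All candidate pairs are reported —
target choice was a manual step in the original workflow, and real loci do
contain overlapping decompositions (one of the four reference amplicons has
three).  `filter_maximal` removes pairs wholly contained in a longer pair at
the same cut position; `rank_pairs` orders by GNN-triplet fraction
(reflecting the published preference for GNN triplets) but this ranking has
no validated correlate.  Enumerating the plus strand is complete: scanning
the reverse complement yields the same pairs with mirrored coordinates (a
property test).

## Assembly simulation

Fragments join when one fragment's 3′ suffix equals another's 5′ prefix over
at least `min_overlap = 21` nt (the designed overlap is the 21 helix codons;
with the shared-codon rule the realized exact overlap is 22 nt, including
one constant framework base).  Chains are simple paths in the resulting
directed graph; maximal chains are those extendable in neither direction.  A
repeated helix creates branch points, several maximal chains and mis-ordered
products — the qualitative misassembly mode observed on real gels; the
simulator flags this rather than suppressing it.  The 3rd PCR retains chains
whose ends regenerate both end primers and reports the band ladder, marking
the on-pathway product.  PCR thermodynamics, yields and volumes are not
modeled; the 2nd-PCR mixing recipe (end fragments 0.5 µl, middle fragments
1.5 µl) is emitted as protocol text only.

TA cloning is modeled as string surgery: blunt cuts at the unique
`CAG^CTG` and `GTA^TAC` sites, stuffer dropped, one 3′ T per end, insert
ligated in both orientations (`backbone + T + insert + A`, circular).  The
synthetic fixture vector arranges frame so the forward construct reads
FLAG–NLS–ZF array–FokI stub as one ORF.  Colony PCR succeeds only with a
forward-orientation insert; an insert-less religation is reported as
`no_insert` with no product (a T3 + insert-specific reverse primer pair
cannot amplify from an empty backbone).

## Genotype classification

Reads are globally aligned to the wild-type amplicon with affine gap scores
(match +1, mismatch −1, gap open −4, extend −0.5; a k-nt gap costs
4 + 0.5·(k−1)).  These defaults make one contiguous gap cheaper than
scattered substitutions, matching the dominant clean-deletion outcome of
NHEJ repair; they are configurable.  Alignment is delegated to a standard
pairwise aligner; an independently written Gotoh dynamic program serves as
the score oracle in the tests.  Of co-optimal alignments the aligner's first
is used — a deterministic tie-break.  Aligned columns tally into
(substitutions, deletions, insertions); `n_ins − n_del` always equals the
length difference.  Labels list nonzero counts largest-first ("3 D, 2 S");
rows that mix a large insertion with substitutions are reported with their
full counts rather than a single-event simplification.  The in-silico T7
endonuclease I assay places the cut at the first non-matching alignment
column in wild-type coordinates, so the two fragment lengths sum to the
amplicon length; for real heteroduplexes the enzyme cuts near, not exactly
at, the bubble, so these lengths are approximate band positions.

## Fixtures: what they do and do not emulate

`make_planted_genome` embeds registry-valid pairs in uniform-random
background; `make_mutant_reads` applies each edit category as a single
contiguous event with deterministic substitution rotation and seeded
insertions.  Fixture sizes used by the tests and the acceptance script are
small (1–2 kb genomes, ~30 reads) — ample for exact string operations.
Passing tests therefore demonstrate correctness of the string-level model,
not robustness to sequencing error, mosaicism, heterozygous chromatogram
mixtures, repetitive genomic context or base-composition bias, none of
which the fixtures contain.  Biological efficiencies (mutation rates,
embryo development rates) are wet-lab outcomes: only the summary-table
*format* is reproduced from fixture truth.

## Numerical and degenerate-input choices

* All comparisons are case-insensitive; mixed case is preserved only as
  annotation metadata.
* Codon tie-breaks and alignment tie-breaks are deterministic; the only
  randomness (fixtures, random-helix checks) flows through a single seeded
  generator.
* Empty or too-short scan input returns an empty result, not an error;
  windows containing `N` are skipped.
* Degenerate assembly input: an empty fragment list yields no products; a
  single fragment passes through unchanged.
* `registry.lookup` is total over the packaged 21 triplets and raises a
  named error for anything else; user overlay entries must pass the same
  structural invariants as packaged ones.

## Known limitations

No melting-temperature or secondary-structure screening of primers; no
genome-scale off-target search or helix-affinity scoring; no prediction of
new helices for unlisted triplets (only design around a given helix); the
internal template framework is a synthetic stand-in at the nucleotide level;
mismatch-tolerant annealing is not modeled, so assemblies that would succeed
at the bench despite a 1-nt overlap mismatch are reported as failures to
join.
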