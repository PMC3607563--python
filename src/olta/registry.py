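"""Catalog of zinc-finger DNA-recognition helices and their 1st-PCR primers.

Each zinc finger binds one DNA triplet through a 7-amino-acid recognition
helix.  The OLTA workflow encodes every helix on a pair of short (29-nt) PCR
primers: the forward primer carries the 21 helix-coding nucleotides followed
by a constant 8-nt tail of the finger framework, the reverse primer carries
the reverse complement of the helix codons embedded in constant framework with
a 7-nt constant 3' anchor.  Once synthesized, one primer pair per triplet is
reusable in any finger position of any array.

The packaged catalog holds the 21 published triplet->helix->primer entries.
Primer sequences are stored in their published mixed case: lowercase marks a
position annotated as differing from the zinc-finger template vector.  The
``fwd_ndn``/``rev_ndn`` columns are the *recorded* mismatch counts (NDN,
"number of different nucleotides") transcribed verbatim; ``validate_registry``
recomputes them against a template model and reports any disagreement rather
than raising, because a handful of recorded counts are known to be internally
inconsistent with their own sequences.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from .sequences import SequenceError, check_dna, translate

FWD_TAIL = "CATATCCG"  #: constant 8-nt 3' tail of every forward primer
REV_ANCHOR = "ACTGAAG"  #: constant 7-nt 3' anchor of every reverse primer
MAX_NDN = 11  #: design cap: at most 11 mismatches to the template per primer
MAX_PRIMER_LEN = 29


class UnknownTripletError(KeyError):
    def __init__(self, triplet: str):
        super().__init__(triplet)
        self.triplet = triplet

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"no helix available for triplet {self.triplet!r}"


@dataclass(frozen=True)
class TripletHelixEntry:
    """One DNA triplet with its recognition helix and 1st-PCR primer pair.

    ``fwd_primer``/``rev_primer`` are uppercase; ``fwd_case``/``rev_case``
    preserve the published mixed-case annotation (lowercase = annotated
    mismatch to the template vector).
    """

    triplet: str
    helix: str
    fwd_primer: str
    rev_primer: str
    fwd_ndn: int
    rev_ndn: int
    fwd_case: str = ""
    rev_case: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "triplet", check_dna(self.triplet, name="triplet"))
        if len(self.triplet) != 3:
            raise SequenceError(f"triplet must be 3 nt, got {self.triplet!r}")
        for attr in ("fwd_primer", "rev_primer"):
            seq = check_dna(getattr(self, attr), name=attr)
            object.__setattr__(self, attr, seq)
            if len(seq) > MAX_PRIMER_LEN:
                raise SequenceError(f"{attr} longer than {MAX_PRIMER_LEN} nt")
        if translate(self.fwd_primer[:21]) != self.helix:
            raise SequenceError(
                f"{self.triplet}: forward primer does not encode helix {self.helix}"
            )
        if not self.fwd_primer.endswith(FWD_TAIL):
            raise SequenceError(f"{self.triplet}: forward primer lacks {FWD_TAIL} tail")
        if not self.rev_primer.endswith(REV_ANCHOR):
            raise SequenceError(f"{self.triplet}: reverse primer lacks {REV_ANCHOR} anchor")
        for attr in ("fwd_ndn", "rev_ndn"):
            if not 0 <= getattr(self, attr) <= MAX_NDN:
                raise SequenceError(f"{self.triplet}: {attr} outside [0, {MAX_NDN}]")

    @staticmethod
    def lowercase_mask(case_annotated: str) -> list[int]:
        """Positions annotated lowercase (recorded template mismatches)."""
        return [i for i, c in enumerate(case_annotated) if c.islower()]


@dataclass
class EntryValidation:
    triplet: str
    fwd_recorded: int
    fwd_recomputed: int
    rev_recorded: int
    rev_recomputed: int

    @property
    def fwd_ok(self) -> bool:
        return self.fwd_recorded == self.fwd_recomputed

    @property
    def rev_ok(self) -> bool:
        return self.rev_recorded == self.rev_recomputed


@dataclass
class ValidationReport:
    entries: list[EntryValidation] = field(default_factory=list)

    @property
    def n_checked(self) -> int:
        return 2 * len(self.entries)

    @property
    def n_pass(self) -> int:
        return sum(e.fwd_ok for e in self.entries) + sum(e.rev_ok for e in self.entries)

    @property
    def all_ok(self) -> bool:
        return self.n_pass == self.n_checked

    def failures(self) -> list[EntryValidation]:
        return [e for e in self.entries if not (e.fwd_ok and e.rev_ok)]


class HelixRegistry:
    """Lookup table triplet -> :class:`TripletHelixEntry`.

    The packaged baseline is immutable; user entries are an overlay on top of
    it and must satisfy the same invariants (``add_entry``).
    """

    def __init__(self, entries: dict[str, TripletHelixEntry] | None = None):
        self._packaged: dict[str, TripletHelixEntry] = dict(entries or {})
        self._user: dict[str, TripletHelixEntry] = {}

    # -- access -----------------------------------------------------------
    def lookup(self, triplet: str) -> TripletHelixEntry:
        key = check_dna(triplet, name="triplet")
        if len(key) != 3:
            raise SequenceError(f"triplet must be 3 nt, got {triplet!r}")
        entry = self._user.get(key) or self._packaged.get(key)
        if entry is None:
            raise UnknownTripletError(key)
        return entry

    def __contains__(self, triplet: str) -> bool:
        key = triplet.upper()
        return key in self._user or key in self._packaged

    def __iter__(self) -> Iterator[TripletHelixEntry]:
        seen = dict(self._packaged)
        seen.update(self._user)
        yield from seen.values()

    def registry_size(self) -> int:
        return len(set(self._packaged) | set(self._user))

    def triplets(self) -> list[str]:
        return sorted(set(self._packaged) | set(self._user))

    # -- mutation ---------------------------------------------------------
    def add_entry(self, entry: TripletHelixEntry) -> None:
        """Overlay a user entry; the packaged baseline is never overwritten."""
        self._user[entry.triplet] = entry

    def load_overlay(self, path: str | Path) -> int:
        """Load user entries from a TSV in the packaged dialect."""
        n = 0
        for entry in _read_tsv(Path(path)):
            self.add_entry(entry)
            n += 1
        return n

    # -- validation -------------------------------------------------------
    def validate_registry(self, template) -> ValidationReport:
        """Recompute every entry's mismatch counts against ``template``.

        Forward primers are compared to the template's forward annealing
        reference, reverse primers to the reverse reference, over all 29
        positions.  Disagreements with the recorded NDN values are reported,
        not raised.
        """
        from .template import count_mismatches

        report = ValidationReport()
        for entry in sorted(self, key=lambda e: e.triplet):
            report.entries.append(
                EntryValidation(
                    triplet=entry.triplet,
                    fwd_recorded=entry.fwd_ndn,
                    fwd_recomputed=count_mismatches(entry.fwd_primer, template.fwd_ref),
                    rev_recorded=entry.rev_ndn,
                    rev_recomputed=count_mismatches(entry.rev_primer, template.rev_ref),
                )
            )
        return report


def _read_tsv(path) -> Iterator[TripletHelixEntry]:
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            yield TripletHelixEntry(
                triplet=row["triplet"],
                helix=row["helix"].upper(),
                fwd_primer=row["fwd_primer"],
                rev_primer=row["rev_primer"],
                fwd_ndn=int(row["fwd_ndn"]),
                rev_ndn=int(row["rev_ndn"]),
                fwd_case=row["fwd_primer"],
                rev_case=row["rev_primer"],
            )


def load_registry() -> HelixRegistry:
    """Load the packaged 21-entry catalog."""
    data = resources.files("olta.data").joinpath("helix_primers.tsv")
    with resources.as_file(data) as path:
        entries = {e.triplet: e for e in _read_tsv(path)}
    return HelixRegistry(entries)
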