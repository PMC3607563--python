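"""Paired ZFN half-site discovery.

A ZFN pair binds its locus as two half-sites on opposite strands separated by
a 5-6 bp spacer where the FokI domains dimerize and cut.  On the plus strand
the arrangement reads

    5' ... [revcomp(left site)] [spacer] [right site] ... 3'

where the left half-site is read 5'->3' on the minus strand and the right
half-site 5'->3' on the plus strand.  Each half-site is a run of 3-bp
triplets, every one of which must have a recognition helix in the registry.
Finger order follows the N-to-C / 3'-to-5' convention: ZF1 (the N-terminal
finger) binds the 3'-most triplet of its half-site.

``scan`` reports every candidate pair (the published sites were hand-picked;
no greedy suppression).  ``filter_maximal`` drops pairs whose half-sites are
both contained in a longer pair at the same cut position -- a 6-finger site
whose 3' 12 bp also decompose into registry triplets would otherwise be
reported again as a 4-finger site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .registry import HelixRegistry, load_registry
from .sequences import SequenceError, check_dna, revcomp


@dataclass
class ScanParams:
    min_fingers: int = 4
    max_fingers: int = 6
    spacer_min: int = 5
    spacer_max: int = 6
    registry: HelixRegistry = field(default_factory=load_registry)
    #: rank output by fraction of GNN triplets (highest first) when True
    prefer_gnn: bool = False

    def __post_init__(self) -> None:
        if not 3 <= self.min_fingers <= self.max_fingers:
            raise ValueError("need 3 <= min_fingers <= max_fingers")
        if not 0 < self.spacer_min <= self.spacer_max:
            raise ValueError("need 0 < spacer_min <= spacer_max")


def finger_order(site_seq: str) -> list[str]:
    """Triplets of a half-site in finger order (ZF1 binds the 3'-most triplet)."""
    site = check_dna(site_seq, name="site_seq")
    if len(site) % 3:
        raise SequenceError(f"site length {len(site)} not divisible by 3")
    triplets = [site[i : i + 3] for i in range(0, len(site), 3)]
    return triplets[::-1]


@dataclass(frozen=True)
class ZfnHalfSite:
    strand: str  # "+" | "-"
    start: int  # 0-based, half-open, on the input plus strand
    end: int
    site_seq: str  # 5'->3' on its own strand

    @property
    def n_fingers(self) -> int:
        return len(self.site_seq) // 3

    @property
    def triplets(self) -> list[str]:
        return [self.site_seq[i : i + 3] for i in range(0, len(self.site_seq), 3)]

    @property
    def zf_order(self) -> list[str]:
        return finger_order(self.site_seq)


@dataclass(frozen=True)
class ZfnSitePair:
    left: ZfnHalfSite  # minus strand, upstream on the plus strand
    right: ZfnHalfSite  # plus strand, downstream
    spacer_seq: str

    @property
    def spacer_len(self) -> int:
        return len(self.spacer_seq)

    @property
    def gnn_fraction(self) -> float:
        trips = self.left.triplets + self.right.triplets
        return sum(t[0] == "G" for t in trips) / len(trips)

    def sort_key(self) -> tuple:
        return (self.left.start, self.left.end, self.right.start, self.right.end)


def _registry_run(seq: str, registry: HelixRegistry) -> bool:
    """Does ``seq`` decompose 5'->3' into registry triplets?"""
    if "N" in seq:
        return False
    return all(seq[i : i + 3] in registry for i in range(0, len(seq), 3))


def scan(seq: str, params: ScanParams | None = None) -> list[ZfnSitePair]:
    """Find all paired half-sites in ``seq``.

    Enumerates every (left fingers, spacer, right fingers) combination within
    the parameter ranges at every position.  The enumeration over the plus
    strand is complete: a pair found by scanning the reverse complement maps
    back to the same (upstream-minus, downstream-plus) arrangement, so no
    second pass is needed; deduplicated, sorted by position.  Asymmetric
    finger counts are allowed.
    """
    params = params or ScanParams()
    s = check_dna(seq, name="seq", allow_n=True)
    reg = params.registry
    pairs: dict[tuple, ZfnSitePair] = {}
    finger_range = range(params.min_fingers, params.max_fingers + 1)
    for a in range(len(s)):
        for n_left in finger_range:
            left_end = a + 3 * n_left
            if left_end > len(s):
                break
            left_window = s[a:left_end]
            left_site = revcomp(left_window)
            if not _registry_run(left_site, reg):
                continue
            for spacer in range(params.spacer_min, params.spacer_max + 1):
                right_start = left_end + spacer
                for n_right in finger_range:
                    right_end = right_start + 3 * n_right
                    if right_end > len(s):
                        break
                    right_window = s[right_start:right_end]
                    if not _registry_run(right_window, reg):
                        continue
                    pair = ZfnSitePair(
                        left=ZfnHalfSite("-", a, left_end, left_site),
                        right=ZfnHalfSite("+", right_start, right_end, right_window),
                        spacer_seq=s[left_end:right_start],
                    )
                    pairs[pair.sort_key()] = pair
    return sorted(pairs.values(), key=lambda p: p.sort_key())


def filter_maximal(pairs: list[ZfnSitePair]) -> list[ZfnSitePair]:
    """Drop pairs dominated by an extension of either half-site.

    ``P`` is dominated by ``Q`` when both share the same spacer (same left
    end and right start) and ``Q``'s half-sites contain ``P``'s.
    """

    def dominated(p: ZfnSitePair, q: ZfnSitePair) -> bool:
        return (
            p is not q
            and q.left.end == p.left.end
            and q.right.start == p.right.start
            and q.left.start <= p.left.start
            and q.right.end >= p.right.end
            and (q.left.start < p.left.start or q.right.end > p.right.end)
        )

    return [p for p in pairs if not any(dominated(p, q) for q in pairs)]


def rank_pairs(pairs: list[ZfnSitePair]) -> list[ZfnSitePair]:
    """Stable ranking by GNN-triplet fraction, highest first (the published
    site search favoured GNN triplets)."""
    return sorted(pairs, key=lambda p: (-p.gnn_fraction,) + p.sort_key())
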