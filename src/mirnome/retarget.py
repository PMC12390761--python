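"""Seed-mutation retargeting by canonical seed-site matching over 3'UTRs.

A mature miRNA recognizes targets mainly through its seed (nt 2-8).  The
canonical site classes in a 3'UTR are:

* ``7mer-m8`` — exact Watson-Crick match to miRNA nt 2-8,
* ``7mer-A1`` — match to nt 2-7 followed by an adenosine opposite nt 1,
* ``8mer``    — both: match to nt 2-8 followed by the A1 adenosine.

For a seed mutation, the wild-type and mutant seeds are scanned over a UTR
database and the two target sets (UTRs with at least one canonical site)
are partitioned into wild-type-only / shared / mutant-only — the class of
analysis usually drawn as a two-set Venn diagram.  Context scoring and
conservation filtering are deliberately not implemented: the comparison is
purely set overlap, a canonical-match approximation of TargetScan-style
prediction.

All sequences are mapped to the DNA alphabet (U->T, uppercase) at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

from .annotate import revcomp

__all__ = [
    "SeedSite",
    "RetargetResult",
    "AmbiguousSeedError",
    "extract_seed",
    "find_canonical_sites",
    "target_set",
    "retarget_overlap",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


class AmbiguousSeedError(ValueError):
    """Seed contains an ambiguous base (N)."""


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    position: int        # 1-based start of the site in the UTR
    site_type: str

    def __post_init__(self):
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.position < 1:
            raise ValueError("site position is 1-based")


@dataclass
class RetargetResult:
    n_wt_only: int
    n_shared: int
    n_mut_only: int

    @property
    def jaccard(self) -> float:
        denom = self.n_wt_only + self.n_shared + self.n_mut_only
        return self.n_shared / denom if denom else 0.0


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def extract_seed(mature_sequence: str) -> str:
    """Seed of a mature miRNA: nucleotides 2-8 (7 nt), alphabet preserved."""
    if len(mature_sequence) < 8:
        raise ValueError(f"mature sequence of {len(mature_sequence)} nt is too short for a seed")
    return mature_sequence[1:8]


def find_canonical_sites(seed: str, utr_sequence: str, utr_id: str = "") -> list[SeedSite]:
    """Scan a UTR for canonical sites of a 7-nt seed (miRNA nt 2-8).

    Matching is on the DNA alphabet, case-insensitive.  Overlapping matches
    are reported once at the strongest type (8mer > 7mer-m8 > 7mer-A1): an
    8mer suppresses the 7mer-m8 at the same start and the 7mer-A1 contained
    within it.  Positions are 1-based starts of the matched site.
    """
    seed = _dna(seed)
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    if "N" in seed:
        raise AmbiguousSeedError(f"seed {seed} contains N")
    utr = _dna(utr_sequence)

    m8_site = revcomp(seed)               # complements miRNA nt 2-8
    a1_site = revcomp(seed[:6]) + "A"     # complements nt 2-7, then A1 adenosine
    mer8_site = m8_site + "A"

    sites: list[SeedSite] = []
    eights = set()
    start = 0
    while (i := utr.find(mer8_site, start)) != -1:
        sites.append(SeedSite(utr_id, i + 1, "8mer"))
        eights.add(i)
        start = i + 1
    start = 0
    while (i := utr.find(m8_site, start)) != -1:
        if i not in eights:
            sites.append(SeedSite(utr_id, i + 1, "7mer-m8"))
        start = i + 1
    start = 0
    while (i := utr.find(a1_site, start)) != -1:
        # the A1 heptamer of an 8mer starts one base into the 8mer
        if (i - 1) not in eights:
            sites.append(SeedSite(utr_id, i + 1, "7mer-A1"))
        start = i + 1
    sites.sort(key=lambda s: (s.position, SITE_TYPES.index(s.site_type)))
    return sites


UtrDb = Union[Mapping[str, str], Sequence[tuple[str, str]]]


def _iter_utrs(utr_db: UtrDb) -> Iterable[tuple[str, str]]:
    if isinstance(utr_db, Mapping):
        return utr_db.items()
    return utr_db


def target_set(seed: str, utr_db: UtrDb) -> set[str]:
    """UTR ids carrying at least one canonical site for the seed."""
    return {uid for uid, seq in _iter_utrs(utr_db) if find_canonical_sites(seed, seq, uid)}


def retarget_overlap(wt_seed: str, mut_seed: str, utr_db: UtrDb) -> RetargetResult:
    """Partition predicted targets of wild-type vs mutant seed.

    Returns the counts of UTRs targeted only by the wild-type seed, by
    both, and only by the mutant seed.
    """
    wt = target_set(wt_seed, utr_db)
    mut = target_set(mut_seed, utr_db)
    return RetargetResult(
        n_wt_only=len(wt - mut),
        n_shared=len(wt & mut),
        n_mut_only=len(mut - wt),
    )
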