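"""Tumor/normal pair identity verification from a small SNP panel.

A handful (by default 10) of unlinked common SNPs (population MAF > 0.1)
are genotyped from allele depths in both members of a pair; genotype
concordance across the panel decides whether the two samples share a
donor.  Unrelated individuals agree on roughly half of such genotypes, so
a concordance threshold of 0.8 separates matched pairs from sample swaps
with a wide margin.

Tumors may lose heterozygosity, so a het<->hom disagreement can optionally
be scored as half-discordant (``loh_half=True``; a full
hom_ref<->hom_alt disagreement always scores 0).  Half-credit is applied
to either direction, keeping the comparison symmetric, but it is off by
default: with a 10-SNP panel it lifts the expected concordance of
unrelated pairs from ~0.39 to ~0.63, close enough to the 0.8 match
threshold that sample swaps start slipping through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "FingerprintPanel",
    "FingerprintReport",
    "genotype_from_depths",
    "pair_concordance",
    "HetBand",
]

GENOTYPES = ("hom_ref", "het", "hom_alt", "nocall")


@dataclass(frozen=True)
class HetBand:
    low: float = 0.15
    high: float = 0.85


@dataclass
class FingerprintPanel:
    """SNPs as (chrom, pos, ref, alt, population_maf)."""

    snps: list

    def __post_init__(self):
        if not self.snps:
            raise ValueError("panel must contain at least one SNP")
        for snp in self.snps:
            maf = snp[4]
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"population MAF {maf} outside (0, 0.5]")

    def __len__(self) -> int:
        return len(self.snps)

    @classmethod
    def from_tsv(cls, path: str) -> "FingerprintPanel":
        snps = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, pos, ref, alt, maf = line.rstrip("\n").split("\t")[:5]
                snps.append((chrom, int(pos), ref, alt, float(maf)))
        return cls(snps)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tmaf\n")
            for chrom, pos, ref, alt, maf in self.snps:
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{maf}\n")


@dataclass
class FingerprintReport:
    pair_id: str
    n_comparable: int
    concordance: float
    verdict: str          # {matched, mismatched, inconclusive}

    def __post_init__(self):
        if not 0.0 <= self.concordance <= 1.0:
            raise ValueError(f"concordance {self.concordance} outside [0,1]")
        if self.verdict not in ("matched", "mismatched", "inconclusive"):
            raise ValueError(f"bad verdict {self.verdict!r}")


def genotype_from_depths(
    ref_count: int,
    alt_count: int,
    min_depth: int = 10,
    het_band: HetBand = HetBand(),
) -> str:
    """Call a diploid genotype from allele depths.

    Depth below ``min_depth`` is a nocall; otherwise the alt-allele
    fraction is thresholded against the het band (defaults 0.15-0.85,
    boundary values inclusive in the het class).
    """
    total = ref_count + alt_count
    if total < min_depth:
        return "nocall"
    frac = alt_count / total
    if frac < het_band.low:
        return "hom_ref"
    if frac > het_band.high:
        return "hom_alt"
    return "het"


def _site_score(a: str, b: str, loh_half: bool) -> Optional[float]:
    """Concordance contribution of one comparable site (None = not comparable)."""
    if a == "nocall" or b == "nocall":
        return None
    if a == b:
        return 1.0
    if loh_half and ("het" in (a, b)):
        return 0.5
    return 0.0


def pair_concordance(
    genotypes_tumor: Sequence[str],
    genotypes_normal: Sequence[str],
    match_threshold: float = 0.8,
    min_comparable: int = 5,
    loh_half: bool = False,
    pair_id: str = "",
) -> FingerprintReport:
    """Compare index-aligned genotype vectors of a tumor/normal pair.

    Concordance is averaged over SNPs called in both samples.  The verdict
    is ``matched`` iff concordance >= match_threshold and at least
    ``min_comparable`` SNPs were comparable; too few comparable SNPs give
    ``inconclusive``, never ``matched``.
    """
    if len(genotypes_tumor) != len(genotypes_normal):
        raise ValueError("genotype vectors must be index-aligned to the same panel")
    for g in (*genotypes_tumor, *genotypes_normal):
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r}")
    scores = [
        s
        for a, b in zip(genotypes_tumor, genotypes_normal)
        if (s := _site_score(a, b, loh_half)) is not None
    ]
    n = len(scores)
    conc = sum(scores) / n if n else 0.0
    if n < min_comparable:
        verdict = "inconclusive"
    elif conc >= match_threshold:
        verdict = "matched"
    else:
        verdict = "mismatched"
    return FingerprintReport(pair_id=pair_id, n_comparable=n, concordance=conc, verdict=verdict)
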