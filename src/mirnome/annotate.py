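"""Somatic variant annotation onto miRNA gene coordinates.

Maps VCF-style variants onto the precursor-relative axis of every
overlapping miRNA gene, renders HGVS ``n.`` strings, classifies the
mutation type, assigns the functional subregion and its miRMut weight, and
records the position within the mature miRNA where applicable.

Alleles are always reported on the *gene* (precursor) strand: a genomic
C>T over a minus-strand gene becomes G>A.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .genemodel import (
    MirnaGene,
    OutOfTargetError,
    Subregion,
    derive_subregions,
    genomic_to_signed,
    signed_to_anchor_offset,
    subregion_weight,
)

__all__ = [
    "Variant",
    "AnnotatedVariant",
    "NormalizationError",
    "GeneIndex",
    "classify_mutation_type",
    "normalize_alleles",
    "annotate_variant",
    "annotate_cohort",
    "hgvs_n",
    "parse_hgvs_n",
    "mirmut_weight",
    "revcomp",
]

mirmut_weight = subregion_weight

_ALLELE_RE = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NormalizationError(ValueError):
    """Ref and alt alleles are identical after trimming."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Variant:
    """A somatic call as read from a tumor/normal VCF."""

    chrom: str
    pos: int                      # 1-based
    ref: str
    alt: str
    sample_id: str = ""
    vaf: Optional[float] = None
    ref_count: Optional[int] = None
    alt_count: Optional[int] = None
    seqq: Optional[float] = None
    germq: Optional[float] = None
    median_base_q: Optional[float] = None
    median_map_q: Optional[float] = None
    filter_status: str = "."

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not _ALLELE_RE.match(self.ref) or not _ALLELE_RE.match(self.alt):
            raise ValueError(f"alleles must be non-empty ACGTN, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0,1]")


@dataclass
class AnnotatedVariant:
    variant: Variant
    gene_id: str
    precursor_coord: tuple[int, int]      # (anchor, offset) of 5'-most affected position
    hgvs_n: str
    mutation_type: str
    subregion_label: str
    weight: float
    arm: str = "none"                     # {5p, 3p, none}
    within_mature_pos: Optional[int] = None
    boundary_warning: bool = False

    def __post_init__(self):
        if self.weight not in (1.0, 1.5, 2.0):
            raise ValueError(f"weight {self.weight} not in {{1.0, 1.5, 2.0}}")
        if (self.within_mature_pos is not None) != (self.arm != "none"):
            raise ValueError("within_mature_pos must be set iff arm is set")


# ---------------------------------------------------------------------------
# allele normalization & mutation-type classification


def normalize_alleles(ref: str, alt: str, pos: int = 1) -> tuple[int, str, str]:
    """Trim shared suffix then prefix; returns (new_pos, ref', alt').

    The minimal alleles may be empty (pure insertion/deletion).  ``new_pos``
    is the 1-based position of the first remaining ref base (for a pure
    insertion, the position of the base *after* which insertion occurs is
    ``new_pos - 1``).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise NormalizationError(f"alleles identical after trim: {ref!r}")
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if not ref and not alt:
        raise NormalizationError("alleles identical after trim")
    return pos, ref, alt


def classify_mutation_type(ref: str, alt: str) -> str:
    """Classify an allele pair after normalization.

    1->1 substitution; 2->2 differing at both positions dinucleotide
    substitution; net gain insertion; net loss deletion; anything else
    complex.
    """
    _, r, a = normalize_alleles(ref, alt)
    if len(r) == 1 and len(a) == 1:
        return "substitution"
    if len(r) == 2 and len(a) == 2:
        # after trimming, both ends necessarily differ
        return "dinucleotide_substitution"
    if not r:
        return "insertion"
    if not a:
        return "deletion"
    return "complex"


# ---------------------------------------------------------------------------
# HGVS "n." rendering and parsing


def _fmt_pos(coord: tuple[int, int]) -> str:
    anchor, offset = coord
    if offset < 0:
        return f"{anchor}{offset}"
    if offset > 0:
        return f"{anchor}+{offset}"
    return str(anchor)


def hgvs_n(coord, ref: str, alt: str, mutation_type: str) -> str:
    """Render an HGVS ``n.`` string from precursor coordinates.

    ``coord`` is a single (anchor, offset) pair, or a
    ((anchor, offset), (anchor, offset)) span for multi-nucleotide events.
    Deleted/replaced residues are stated explicitly (``n.5_7delACT``) so the
    string round-trips to (coord, ref, alt) without a reference lookup.
    """
    if coord and isinstance(coord[0], tuple):
        start, end = coord
    else:
        start = end = coord
    s, e = _fmt_pos(start), _fmt_pos(end)
    if mutation_type == "substitution":
        return f"n.{s}{ref}>{alt}"
    if mutation_type == "dinucleotide_substitution" or mutation_type == "complex":
        return f"n.{s}_{e}del{ref}ins{alt}"
    if mutation_type == "deletion":
        return f"n.{s}del{ref}" if start == end else f"n.{s}_{e}del{ref}"
    if mutation_type == "insertion":
        return f"n.{s}_{e}ins{alt}"
    raise ValueError(f"unknown mutation type {mutation_type!r}")


_POS_RE = r"(\d+)([+-]\d+)?"
_HGVS_RES = [
    ("substitution", re.compile(rf"^n\.{_POS_RE}([ACGTN])>([ACGTN])$")),
    ("delins", re.compile(rf"^n\.{_POS_RE}(?:_{_POS_RE})?del([ACGTN]+)ins([ACGTN]+)$")),
    ("deletion", re.compile(rf"^n\.{_POS_RE}(?:_{_POS_RE})?del([ACGTN]*)$")),
    ("insertion", re.compile(rf"^n\.{_POS_RE}_{_POS_RE}ins([ACGTN]+)$")),
]


def _parse_pos(anchor: str, offset: Optional[str]) -> tuple[int, int]:
    return (int(anchor), int(offset) if offset else 0)


def parse_hgvs_n(s: str):
    """Parse an emitted HGVS ``n.`` string back to (start, end, ref, alt, type)."""
    for kind, rx in _HGVS_RES:
        m = rx.match(s)
        if not m:
            continue
        g = m.groups()
        if kind == "substitution":
            p = _parse_pos(g[0], g[1])
            return p, p, g[2], g[3], "substitution"
        if kind == "delins":
            start = _parse_pos(g[0], g[1])
            end = _parse_pos(g[2], g[3]) if g[2] else start
            ref, alt = g[4], g[5]
            mt = "dinucleotide_substitution" if len(ref) == len(alt) == 2 else "complex"
            return start, end, ref, alt, mt
        if kind == "deletion":
            start = _parse_pos(g[0], g[1])
            end = _parse_pos(g[2], g[3]) if g[2] else start
            return start, end, g[4], "", "deletion"
        if kind == "insertion":
            start = _parse_pos(g[0], g[1])
            end = _parse_pos(g[2], g[3])
            return start, end, "", g[4], "insertion"
    raise ValueError(f"unparseable HGVS n. string {s!r}")


# ---------------------------------------------------------------------------
# gene index and annotation


class GeneIndex:
    """Interval index of gene target spans (precursor +/- flank) by chromosome."""

    def __init__(self, genes: Sequence[MirnaGene], **subregion_kwargs):
        self._trees: dict[str, IntervalTree] = {}
        self._subregions: dict[str, list[Subregion]] = {}
        self.genes = {g.gene_id: g for g in genes}
        for gene in genes:
            span = gene.target_span
            self._trees.setdefault(span.chrom, IntervalTree()).addi(span.start, span.end, gene)
            if gene.confidence == "high":
                self._subregions[gene.gene_id] = derive_subregions(
                    gene, on_short_arm="duplex", **subregion_kwargs
                )

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[MirnaGene]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start0, end0), key=lambda iv: (iv.begin, iv.data.gene_id))
        return [iv.data for iv in hits]

    def subregions(self, gene_id: str) -> list[Subregion]:
        return self._subregions[gene_id]


def _arm_hit(gene: MirnaGene, signed: int) -> tuple[str, Optional[int]]:
    for arm in ("5p", "3p"):
        if getattr(gene, f"mature_{arm}") is None:
            continue
        s, e = gene.arm_span_rel(arm)
        if s <= signed <= e:
            return arm, signed - s + 1
    return "none", None


def annotate_variant(
    variant: Variant,
    gene_index: GeneIndex,
    indel_assignment: str = "leftmost",
) -> list[AnnotatedVariant]:
    """Annotate a variant against every overlapping miRNA gene.

    A variant inside two clustered genes yields one record per gene.  A
    variant overlapping no gene returns an empty list.  Indels are assigned
    the subregion of their 5'-most affected precursor position by default
    (``indel_assignment="highest_weight"`` picks the best-weighted
    overlapped position instead).  Indels running over the target boundary
    are annotated to the overlapping portion and flagged.
    """
    pos_min, ref_min, alt_min = normalize_alleles(variant.ref, variant.alt, variant.pos)
    mtype = classify_mutation_type(variant.ref, variant.alt)

    # genomic footprint of the event (0-based half-open)
    if ref_min:
        g_start0, g_end0 = pos_min - 1, pos_min - 1 + len(ref_min)
    else:  # pure insertion: between pos_min-1 and pos_min
        g_start0, g_end0 = pos_min - 2, pos_min

    out: list[AnnotatedVariant] = []
    for gene in gene_index.overlapping(variant.chrom, g_start0, g_end0):
        if gene.confidence != "high":
            continue
        subregions = gene_index.subregions(gene.gene_id)
        L = gene.precursor_len

        if gene.strand == "+":
            ref_g, alt_g = ref_min, alt_min
        else:
            ref_g, alt_g = revcomp(ref_min), revcomp(alt_min)

        # signed positions of every affected reference base, in gene 5'->3' order
        boundary = False
        if ref_min:
            genomic_positions = range(pos_min, pos_min + len(ref_min))
            signed_all = []
            for gp in genomic_positions:
                try:
                    signed_all.append(genomic_to_signed(gene, gp))
                except OutOfTargetError:
                    boundary = True
            if not signed_all:
                continue
            signed_all.sort()
        else:
            # insertion: anchor at the two flanking bases, gene-strand order
            cands = []
            for gp in (pos_min - 1, pos_min):
                try:
                    cands.append(genomic_to_signed(gene, gp))
                except OutOfTargetError:
                    boundary = True
            if not cands:
                continue
            signed_all = sorted(cands)

        if indel_assignment == "highest_weight" and mtype not in ("substitution",):
            best = max(
                signed_all,
                key=lambda p: label_weight_at(subregions, p, gene),
            )
            anchor_signed = best
        else:
            anchor_signed = signed_all[0]

        sub = _label_at(subregions, anchor_signed)
        arm, within = _arm_hit(gene, anchor_signed)

        start_coord = signed_to_anchor_offset(signed_all[0], L)
        end_coord = signed_to_anchor_offset(signed_all[-1], L)
        if mtype == "substitution":
            hg = hgvs_n(start_coord, ref_g, alt_g, mtype)
        else:
            hg = hgvs_n((start_coord, end_coord), ref_g, alt_g, mtype)

        out.append(
            AnnotatedVariant(
                variant=variant,
                gene_id=gene.gene_id,
                precursor_coord=signed_to_anchor_offset(anchor_signed, L),
                hgvs_n=hg,
                mutation_type=mtype,
                subregion_label=sub.label,
                weight=sub.weight,
                arm=arm,
                within_mature_pos=within,
                boundary_warning=boundary,
            )
        )
    return out


def _label_at(subregions, pos):
    from .genemodel import label_position

    return label_position(subregions, pos)


def label_weight_at(subregions, pos, gene) -> float:
    return _label_at(subregions, pos).weight


def annotate_cohort(
    variants: Sequence[Variant],
    gene_index: GeneIndex,
    indel_assignment: str = "leftmost",
) -> list[AnnotatedVariant]:
    """Annotate a list of variants; output order follows (chrom, pos, sample)."""
    out: list[AnnotatedVariant] = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.sample_id, v.ref, v.alt)):
        out.extend(annotate_variant(v, gene_index, indel_assignment=indel_assignment))
    return out
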