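"""Coordinate model for miRNA genes on a targeted sequencing panel.

A miRNA gene is defined as the hairpin precursor (pre-miRNA) annotated in a
miRBase-style GFF3, extended by a fixed flank on each side (default 25 nt).
All downstream analyses work in *precursor-relative* coordinates: position 1
is the first nucleotide of the precursor on the gene strand, position L the
last.  Flank positions are addressed relative to these anchors, HGVS style:
16 nt upstream of the precursor is ``1-16``, 3 nt downstream is ``L+3``.

Internally a single signed axis is used: ``-F .. -1`` for the upstream
flank, ``1 .. L`` for the precursor, ``L+1 .. L+F`` for the downstream
flank.  There is no position 0.

Functional subregions tile this axis without gaps: the 5' flank, the two
duplex arms (the guide arm split into pre-seed / seed / post-seed; the
passenger arm as one block), the apical loop, and the 3' flank.  DROSHA and
DICER1 cleavage-site windows and user-supplied protein-binding motifs are
*overlays* on top of the tiling and take precedence when a position is
labeled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "MirnaGene",
    "Subregion",
    "AnnotationError",
    "GFF3ParseError",
    "OutOfTargetError",
    "SeedTruncationError",
    "load_gene_annotations",
    "derive_subregions",
    "label_position",
    "genomic_to_precursor",
    "precursor_to_genomic",
    "signed_to_anchor_offset",
    "anchor_offset_to_signed",
    "subregion_weight",
]

SEED_START = 2   # seed = mature miRNA nt 2-8
SEED_END = 8
DEFAULT_FLANK_LEN = 25


class AnnotationError(ValueError):
    """A gene annotation violates the model's structural assumptions."""


class GFF3ParseError(AnnotationError):
    """A GFF3 line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class OutOfTargetError(ValueError):
    """A genomic position falls outside the precursor +/- flank span."""


class SeedTruncationError(AnnotationError):
    """A mature arm is too short (<8 nt) to carry a full seed."""


@dataclass(frozen=True)
class GenomicInterval:
    """Genomic span, 0-based half-open, with strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class MirnaGene:
    """A pre-miRNA with its annotated mature arms and flanks.

    ``mature_5p`` is the arm nearer the precursor 5' end *in gene
    orientation*; at least one arm must be present.  Genes whose GFF3 record
    had no mature child are flagged ``confidence="low"``.
    """

    gene_id: str
    name: str
    precursor: GenomicInterval
    mature_5p: Optional[GenomicInterval] = None
    mature_3p: Optional[GenomicInterval] = None
    flank_len: int = DEFAULT_FLANK_LEN
    confidence: str = "high"

    def __post_init__(self):
        if self.flank_len < 0:
            raise AnnotationError("flank_len must be >= 0")
        if self.confidence == "high" and self.mature_5p is None and self.mature_3p is None:
            raise AnnotationError(
                f"{self.gene_id}: high-confidence gene requires at least one mature arm"
            )
        for arm in (self.mature_5p, self.mature_3p):
            if arm is not None and not self.precursor.contains(arm):
                raise AnnotationError(
                    f"{self.gene_id}: mature arm {arm} not nested in precursor"
                )
        if self.mature_5p is not None and self.mature_3p is not None:
            a = self.arm_span_rel("5p")
            b = self.arm_span_rel("3p")
            if a[1] >= b[0]:
                raise AnnotationError(
                    f"{self.gene_id}: 5p arm must lie upstream of 3p arm in gene orientation"
                )

    @property
    def strand(self) -> str:
        return self.precursor.strand

    @property
    def precursor_len(self) -> int:
        return len(self.precursor)

    def arm_span_rel(self, arm: str) -> tuple[int, int]:
        """Precursor-relative 1-based inclusive span of an annotated arm."""
        iv = self.mature_5p if arm == "5p" else self.mature_3p
        if iv is None:
            raise AnnotationError(f"{self.gene_id}: arm {arm} not annotated")
        if self.strand == "+":
            return (iv.start - self.precursor.start + 1, iv.end - self.precursor.start)
        return (self.precursor.end - iv.end + 1, self.precursor.end - iv.start)

    @property
    def target_span(self) -> GenomicInterval:
        """Genomic span of precursor plus both flanks."""
        return GenomicInterval(
            self.precursor.chrom,
            self.precursor.start - self.flank_len,
            self.precursor.end + self.flank_len,
            self.strand,
        )

    @property
    def target_len(self) -> int:
        return self.precursor_len + 2 * self.flank_len


@dataclass(frozen=True)
class Subregion:
    """A functional subregion on the signed precursor axis (inclusive)."""

    label: str
    start: int
    end: int
    weight: float
    guide: bool = False
    overlay: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"subregion {self.label}: start {self.start} > end {self.end}")
        if self.start == 0 or self.end == 0:
            raise ValueError("signed precursor axis has no position 0")

    def __len__(self) -> int:
        # inclusive span on an axis without 0
        n = self.end - self.start + 1
        if self.start < 0 < self.end:
            n -= 1
        return n

    def covers(self, pos: int) -> bool:
        return self.start <= pos <= self.end and pos != 0


# ---------------------------------------------------------------------------
# signed axis <-> anchor/offset


def signed_to_anchor_offset(pos: int, precursor_len: int) -> tuple[int, int]:
    """Convert a signed precursor position to (anchor, offset) HGVS style."""
    if pos == 0:
        raise ValueError("no position 0 on the signed precursor axis")
    if pos < 0:
        return (1, pos)
    if pos <= precursor_len:
        return (pos, 0)
    return (precursor_len, pos - precursor_len)


def anchor_offset_to_signed(anchor: int, offset: int, precursor_len: int) -> int:
    if offset < 0:
        if anchor != 1:
            raise ValueError("negative offsets anchor at position 1")
        return offset
    if offset > 0:
        if anchor != precursor_len:
            raise ValueError("positive offsets anchor at the last precursor position")
        return precursor_len + offset
    if not 1 <= anchor <= precursor_len:
        raise ValueError(f"anchor {anchor} outside precursor 1..{precursor_len}")
    return anchor


# ---------------------------------------------------------------------------
# weights

_DUPLEX_LABELS = frozenset(
    {"preseed", "postseed", "passenger_arm_part", "duplex", "cleavage_site", "protein_motif"}
)


def subregion_weight(label: str, guide: bool = False) -> float:
    """miRMut multiplier for a subregion label.

    Seed positions count 2x on the guide strand only; duplex, cleavage-site
    and protein-motif positions 1.5x; flanks, the apical loop (and a seed
    label on a non-guide arm) 1x.
    """
    if label == "seed":
        return 2.0 if guide else 1.0
    if label in _DUPLEX_LABELS:
        return 1.5
    return 1.0


# ---------------------------------------------------------------------------
# GFF3 loading (miRBase dialect)

_GFF_COLS = 9


def _prescan_gff3(lines: Iterable[str]) -> None:
    """Validate basic GFF3 structure so parse errors carry line numbers."""
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != _GFF_COLS:
            raise GFF3ParseError(f"expected {_GFF_COLS} tab-separated columns, found {len(cols)}", i)
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise GFF3ParseError(f"non-integer coordinates {cols[3]!r}/{cols[4]!r}", i) from None
        if start > end:
            raise GFF3ParseError(f"start {start} > end {end}", i)
        if cols[6] not in ("+", "-"):
            raise GFF3ParseError(f"strand must be '+' or '-', found {cols[6]!r}", i)


def _which_arm(gene_strand: str, prec: GenomicInterval, arm: GenomicInterval,
               name: str) -> str:
    """Assign an arm to 5p/3p: trust a -5p/-3p name suffix, else orientation."""
    m = re.search(r"-(5p|3p)$", name or "")
    if m:
        return m.group(1)
    if gene_strand == "+":
        mid_arm = (arm.start + arm.end) / 2
        mid_prec = (prec.start + prec.end) / 2
        return "5p" if mid_arm < mid_prec else "3p"
    mid_arm = (arm.start + arm.end) / 2
    mid_prec = (prec.start + prec.end) / 2
    return "5p" if mid_arm > mid_prec else "3p"


def load_gene_annotations(gff3_source: str, flank_len: int = DEFAULT_FLANK_LEN) -> list[MirnaGene]:
    """Load miRNA genes from a miRBase-dialect GFF3 file.

    Expects ``miRNA_primary_transcript`` features with ``miRNA`` children
    linked by ``Derives_from``.  Precursors without any mature child are
    returned flagged ``confidence="low"``.  Duplicate precursor IDs are
    rejected.
    """
    with open(gff3_source) as fh:
        _prescan_gff3(fh)
    db = gffutils.create_db(
        gff3_source,
        dbfn=":memory:",
        force=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    precursors: dict[str, gffutils.Feature] = {}
    matures: dict[str, list[gffutils.Feature]] = {}
    for feat in db.all_features():
        if feat.featuretype == "miRNA_primary_transcript":
            fid = feat.attributes.get("ID", [feat.id])[0]
            if fid in precursors:
                raise AnnotationError(f"duplicate precursor ID {fid!r}")
            precursors[fid] = feat
        elif feat.featuretype == "miRNA":
            parent = feat.attributes.get("Derives_from", feat.attributes.get("Parent", [None]))[0]
            if parent is None:
                raise AnnotationError(
                    f"mature record {feat.attributes.get('ID', ['?'])[0]} has no Derives_from/Parent"
                )
            matures.setdefault(parent, []).append(feat)

    genes: list[MirnaGene] = []
    for fid, feat in precursors.items():
        prec = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        name = feat.attributes.get("Name", [fid])[0]
        arms: dict[str, GenomicInterval] = {}
        for child in matures.get(fid, []):
            iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
            if not prec.contains(iv):
                raise AnnotationError(
                    f"{fid}: mature record {child.attributes.get('Name', ['?'])[0]} "
                    f"not nested in its parent precursor"
                )
            arm_name = child.attributes.get("Name", [""])[0]
            arm = _which_arm(feat.strand, prec, iv, arm_name)
            if arm in arms:
                raise AnnotationError(f"{fid}: two mature records assigned to arm {arm}")
            arms[arm] = iv
        confidence = "high" if arms else "low"
        genes.append(
            MirnaGene(
                gene_id=fid,
                name=name,
                precursor=prec,
                mature_5p=arms.get("5p"),
                mature_3p=arms.get("3p"),
                flank_len=flank_len,
                confidence=confidence,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# subregion derivation


def _infer_passenger(guide_span: tuple[int, int], precursor_len: int,
                     overhang: int) -> tuple[int, int]:
    """Mirror the guide arm across the hairpin with a 2-nt 3' overhang.

    Position p on one strand of the stem pairs with L+1-p on the other; the
    passenger duplex strand is shifted toward the precursor 5' end by
    ``overhang`` so each duplex end carries the canonical 2-nt 3' overhang.
    """
    a1, a2 = guide_span
    s = precursor_len + 1 - a2 - overhang
    e = precursor_len + 1 - a1 - overhang
    return (max(1, s), min(precursor_len, e))


def _split_guide_arm(span: tuple[int, int], on_short_arm: str) -> list[tuple[str, int, int]]:
    a1, a2 = span
    if a2 - a1 + 1 < SEED_END:
        if on_short_arm == "raise":
            raise SeedTruncationError(
                f"mature arm of {a2 - a1 + 1} nt is too short for a full seed"
            )
        return [("passenger_arm_part", a1, a2)]
    parts = [("preseed", a1, a1), ("seed", a1 + SEED_START - 1, a1 + SEED_END - 1)]
    if a1 + SEED_END <= a2:
        parts.append(("postseed", a1 + SEED_END, a2))
    return parts


def derive_subregions(
    gene: MirnaGene,
    cleavage_window: int = 2,
    passenger_overhang: int = 2,
    guide_arms: Optional[Sequence[str]] = None,
    motifs: Sequence[tuple[int, int]] = (),
    on_short_arm: str = "raise",
) -> list[Subregion]:
    """Tile a gene's signed axis into functional subregions plus overlays.

    Parameters
    ----------
    guide_arms
        Arms whose seed is weighted 2x.  ``None`` (default) treats every
        *annotated* arm as a guide; pass e.g. ``["5p"]`` to restrict seed
        weighting to a dominant arm.  An inferred (unannotated) passenger
        arm is never a guide.
    motifs
        Protein-binding motif overlays as (start, end) signed spans.
    on_short_arm
        ``"raise"`` (default) raises :class:`SeedTruncationError` for arms
        shorter than 8 nt; ``"duplex"`` keeps them as undivided duplex.
    """
    L, F = gene.precursor_len, gene.flank_len

    annotated = {a for a in ("5p", "3p") if getattr(gene, f"mature_{a}") is not None}
    if not annotated:
        raise AnnotationError(f"{gene.gene_id}: no mature arm to derive subregions from")
    if guide_arms is None:
        guides = set(annotated)
    else:
        guides = set(guide_arms) & annotated

    spans: dict[str, tuple[int, int]] = {a: gene.arm_span_rel(a) for a in annotated}
    inferred: set[str] = set()
    if "5p" not in spans:
        spans["5p"] = _infer_passenger(spans["3p"], L, passenger_overhang)
        inferred.add("5p")
    if "3p" not in spans:
        spans["3p"] = _infer_passenger(spans["5p"], L, passenger_overhang)
        inferred.add("3p")
    # an inferred arm must not run into the annotated one
    if spans["5p"][1] >= spans["3p"][0]:
        if "5p" in inferred:
            spans["5p"] = (spans["5p"][0], spans["3p"][0] - 1)
        elif "3p" in inferred:
            spans["3p"] = (spans["5p"][1] + 1, spans["3p"][1])
        if spans["5p"][1] >= spans["3p"][0]:
            raise AnnotationError(f"{gene.gene_id}: arms overlap in precursor coordinates")

    (a1, a2), (b1, b2) = spans["5p"], spans["3p"]

    regions: list[Subregion] = []

    def emit(label: str, start: int, end: int, guide: bool = False, overlay: bool = False):
        if start == 0:
            start = 1 if end > 0 else -1
        if end == 0:
            end = -1 if start < 0 else 1
        if start > end:
            return
        regions.append(
            Subregion(label, start, end, subregion_weight(label, guide), guide, overlay)
        )

    # base tiling: flank5 | arm5 | loop | arm3 | flank3  (axis skips 0)
    if F > 0 or a1 > 1:
        emit("flank5", -F if F else 1, a1 - 1 if a1 > 1 else -1)

    for arm, (s, e) in (("5p", (a1, a2)), ("3p", (b1, b2))):
        if arm in guides:
            for label, ps, pe in _split_guide_arm((s, e), on_short_arm):
                emit(label, ps, pe, guide=(label in ("preseed", "seed", "postseed")))
        else:
            emit("passenger_arm_part", s, e)

    emit("loop", a2 + 1, b1 - 1)
    if F > 0 or b2 < L:
        emit("flank3", b2 + 1, L + F)

    # overlays: DROSHA cleaves at the duplex base, DICER1 below the loop.
    # Each scissile phosphate sits between two nucleotides; the window of
    # width w covers w nt centred on it (w=2 -> one nt each side).
    half = cleavage_window // 2
    rest = cleavage_window - half
    for phosphate in (a1 - 1, a2, b1 - 1, b2):
        s = phosphate - half + 1
        e = phosphate + rest
        s = max(s if s != 0 else -1, -F if F else 1)
        e = min(e if e != 0 else 1, L + F)
        if s <= e:
            emit("cleavage_site", s, e, overlay=True)
    for ms, me in motifs:
        emit("protein_motif", ms, me, overlay=True)

    return regions


_PRECEDENCE = {
    "seed": 0,
    "cleavage_site": 1,
    "protein_motif": 2,
    "preseed": 3,
    "postseed": 3,
    "passenger_arm_part": 3,
    "loop": 4,
    "flank5": 4,
    "flank3": 4,
}


def label_position(subregions: Sequence[Subregion], pos: int) -> Subregion:
    """Pick the subregion labeling a signed position: highest weight wins,
    seed > cleavage site / motif > duplex > loop / flank on ties."""
    hits = [r for r in subregions if r.covers(pos)]
    if not hits:
        raise OutOfTargetError(f"position {pos} not covered by any subregion")
    return min(hits, key=lambda r: (-r.weight, _PRECEDENCE.get(r.label, 9)))


# ---------------------------------------------------------------------------
# coordinate transforms


def genomic_to_signed(gene: MirnaGene, genomic_pos: int) -> int:
    """Map a 1-based genomic position to the gene's signed precursor axis."""
    g0 = genomic_pos - 1
    prec = gene.precursor
    if gene.strand == "+":
        rel = g0 - prec.start + 1
    else:
        rel = prec.end - g0
    signed = rel if rel >= 1 else rel - 1
    if signed < -gene.flank_len or signed > gene.precursor_len + gene.flank_len:
        raise OutOfTargetError(
            f"{gene.gene_id}: genomic position {genomic_pos} outside precursor +/- {gene.flank_len} nt"
        )
    return signed


def genomic_to_precursor(gene: MirnaGene, genomic_pos: int) -> tuple[int, int]:
    """Map a 1-based genomic position to (anchor, offset) precursor coordinates.

    Inside the precursor the result is (n, 0) with n in 1..L; in the
    upstream flank (1, -k); in the downstream flank (L, +k).
    """
    return signed_to_anchor_offset(genomic_to_signed(gene, genomic_pos), gene.precursor_len)


def precursor_to_genomic(gene: MirnaGene, coord) -> int:
    """Inverse of :func:`genomic_to_precursor`; accepts (anchor, offset) or a
    signed position.  Returns a 1-based genomic position."""
    if isinstance(coord, tuple):
        signed = anchor_offset_to_signed(coord[0], coord[1], gene.precursor_len)
    else:
        signed = int(coord)
    if signed == 0:
        raise ValueError("no position 0 on the signed precursor axis")
    if signed < -gene.flank_len or signed > gene.precursor_len + gene.flank_len:
        raise OutOfTargetError(f"{gene.gene_id}: signed position {signed} outside target")
    rel = signed if signed > 0 else signed + 1
    prec = gene.precursor
    if gene.strand == "+":
        return prec.start + rel  # 0-based start + 1-based rel -> 1-based genomic
    return prec.end - rel + 1
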