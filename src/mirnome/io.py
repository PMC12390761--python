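"""File-format plumbing: VCF reading, annotated-variant TSV/VCF output."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from cyvcf2 import VCF

from .annotate import AnnotatedVariant, Variant

__all__ = ["read_vcf_variants", "write_annotated_tsv", "write_annotated_vcf", "ANNOTATED_COLUMNS"]


def _scalar(x):
    if x is None:
        return None
    try:
        return float(x[0]) if hasattr(x, "__len__") and not isinstance(x, str) else float(x)
    except (TypeError, ValueError, IndexError):
        return None


def read_vcf_variants(path, sample_id: Optional[str] = None) -> list[Variant]:
    """Read somatic calls from a VCF 4.2 file.

    AF is taken from FORMAT (or derived from AD when absent); the Mutect2
    quality annotations SEQQ/GERMQ/MBQ/MMQ are accepted from INFO or FORMAT.
    Multi-allelic records yield one :class:`Variant` per alt allele.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if sample_id is None:
        sample_id = samples[0] if samples else Path(str(path)).stem
    si = samples.index(sample_id) if sample_id in samples else 0

    def fmt_or_info(rec, tag):
        val = rec.INFO.get(tag)
        if val is not None:
            return _scalar(val)
        try:
            arr = rec.format(tag)
        except KeyError:
            return None
        if arr is None:
            return None
        return _scalar(arr[si])

    out: list[Variant] = []
    for rec in vcf:
        ref = rec.REF
        ad = None
        try:
            ad_arr = rec.format("AD")
            if ad_arr is not None:
                ad = ad_arr[si]
        except KeyError:
            pass
        for ai, alt in enumerate(rec.ALT):
            vaf = None
            try:
                af_arr = rec.format("AF")
                if af_arr is not None:
                    vaf = _scalar(af_arr[si])
            except KeyError:
                pass
            ref_count = alt_count = None
            if ad is not None and len(ad) > ai + 1:
                ref_count, alt_count = int(ad[0]), int(ad[ai + 1])
                if vaf is None and ref_count + alt_count > 0:
                    vaf = alt_count / (ref_count + alt_count)
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=ref,
                    alt=alt,
                    sample_id=sample_id,
                    vaf=vaf,
                    ref_count=ref_count,
                    alt_count=alt_count,
                    seqq=fmt_or_info(rec, "SEQQ"),
                    germq=fmt_or_info(rec, "GERMQ"),
                    median_base_q=fmt_or_info(rec, "MBQ"),
                    median_map_q=fmt_or_info(rec, "MMQ"),
                    filter_status=rec.FILTER or "PASS",
                )
            )
    return out


ANNOTATED_COLUMNS = (
    "sample_id", "chrom", "pos", "ref", "alt", "gene_id", "hgvs_n",
    "mutation_type", "subregion", "weight", "arm", "within_mature_pos", "vaf",
)


def write_annotated_tsv(path, annotated: Sequence[AnnotatedVariant]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATED_COLUMNS) + "\n")
        for av in annotated:
            v = av.variant
            row = (
                v.sample_id, v.chrom, str(v.pos), v.ref, v.alt, av.gene_id, av.hgvs_n,
                av.mutation_type, av.subregion_label, f"{av.weight:g}", av.arm,
                "" if av.within_mature_pos is None else str(av.within_mature_pos),
                "" if v.vaf is None else f"{v.vaf:.4f}",
            )
            fh.write("\t".join(row) + "\n")


def write_annotated_vcf(path, annotated: Sequence[AnnotatedVariant], contigs: dict) -> None:
    """Annotated output as VCF with MIRGENE/HGVSN/SUBREGION/MIRMUT_W INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        for tag, typ, desc in (
            ("MIRGENE", "String", "miRNA gene id"),
            ("HGVSN", "String", "HGVS n. annotation on the precursor"),
            ("SUBREGION", "String", "Functional subregion label"),
            ("MIRMUT_W", "Float", "miRMut functional weight"),
        ):
            fh.write(f'##INFO=<ID={tag},Number=1,Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for av in sorted(annotated, key=lambda a: (a.variant.chrom, a.variant.pos, a.gene_id)):
            v = av.variant
            info = (
                f"MIRGENE={av.gene_id};HGVSN={av.hgvs_n};"
                f"SUBREGION={av.subregion_label};MIRMUT_W={av.weight:g}"
            )
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\n")
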