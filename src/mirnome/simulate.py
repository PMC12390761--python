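"""Synthetic whole-miRNome cohort generator with a planted-truth ledger.

Emulates the study design the pipeline targets: a genome carrying a few
hundred miRNA hairpin genes, tumor/normal pairs whose tumor VCFs contain
somatic calls planted at configurable per-subregion rates, records that
deliberately violate each somatic filter, a common-SNP blacklist, an
unlinked-SNP fingerprint panel with optional sample swaps, and a 3'UTR
database with planted canonical seed-match sites.

Every emitted VCF record traces to exactly one row of the
:class:`SyntheticTruth` mutation ledger, enabling end-to-end recovery
tests.  All randomness flows from a single seed; the same seed reproduces
byte-identical outputs.

Hairpin sequences are random bases: coordinates, not foldability, drive
every implemented analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .annotate import Variant, revcomp
from .genemodel import (
    GenomicInterval,
    MirnaGene,
    derive_subregions,
    genomic_to_signed,
    label_position,
    precursor_to_genomic,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "SimulatedCohort", "GenerationError", "simulate_cohort"]

BASES = "ACGT"

# base-tiling labels whose planted rates can be configured independently
RATE_LABELS = ("flank5", "preseed", "seed", "postseed", "passenger_arm_part", "loop", "flank3")


class GenerationError(RuntimeError):
    pass


def _default_rates() -> dict[str, float]:
    # uniform placement at the study's average density (mut/Mb per sample)
    return {label: 15.0 for label in RATE_LABELS}


@dataclass
class SimulationConfig:
    rng_seed: int
    n_genes: int = 200
    precursor_len_range: tuple[int, int] = (55, 95)
    mature_len_range: tuple[int, int] = (19, 23)
    flank_len: int = 25
    n_sample_pairs: int = 50
    per_subregion_rates: dict = field(default_factory=_default_rates)
    vaf_beta: tuple[float, float] = (2.0, 6.0)
    min_vaf: float = 0.05
    fraction_below_vaf_cut: float = 0.10
    fraction_common_snp: float = 0.05
    fraction_low_quality: float = 0.05
    mutation_type_probs: tuple[float, float, float, float] = (0.939, 0.032, 0.015, 0.015)
    single_arm_fraction: float = 0.10
    n_snp_panel: int = 10
    snp_maf_range: tuple[float, float] = (0.35, 0.5)
    n_swapped_pairs: int = 0
    n_blacklist_sites: int = 20
    n_utrs: int = 60
    utr_len: int = 500
    planted_site_counts: tuple[int, int, int] = (12, 8, 10)   # wt-only, shared, mut-only
    sequencing_depth: int = 700

    def __post_init__(self):
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory")
        for lo, hi in (self.precursor_len_range, self.mature_len_range):
            if lo > hi:
                raise ValueError("length ranges must be ordered")
        if any(r < 0 for r in self.per_subregion_rates.values()):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        """Load a config from a flat-key YAML file; kwargs override."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("precursor_len_range", "mature_len_range", "vaf_beta",
                    "mutation_type_probs", "snp_maf_range", "planted_site_counts"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class MutationTruth:
    sample_id: str
    pair_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str
    signed_pos: int
    subregion: str
    weight: float
    vaf: float
    mutation_type: str
    should_pass_filters: bool
    fail_reason: str = ""


@dataclass
class SyntheticTruth:
    genes: list = field(default_factory=list)          # dict rows
    mutations: list = field(default_factory=list)      # MutationTruth rows
    swapped_pairs: list = field(default_factory=list)  # pair ids
    utr_sites: dict = field(default_factory=dict)      # utr_id -> wt_only/shared/mut_only/none
    wt_seed: str = ""
    mut_seed: str = ""


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    genome: dict
    genes: list
    variants: dict                     # sample_id -> list[Variant]
    snp_blacklist: frozenset
    panel_snps: list                   # (chrom, pos, ref, alt, maf)
    fingerprint_depths: dict           # (pair_id, 'T'|'N') -> list[(ref_count, alt_count)]
    utrs: dict                         # utr_id -> sequence
    truth: SyntheticTruth

    @property
    def pair_ids(self) -> list:
        return [f"P{i + 1:03d}" for i in range(self.config.n_sample_pairs)]

    # ------------------------------------------------------------------ IO
    def write(self, outdir) -> None:
        """Write genome FASTA, GFF3, per-pair VCFs, panel/depth TSVs, UTR
        FASTA, blacklist TSV, and the truth ledgers under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_gff3(out / "genes.gff3", self.genes)
        write_fasta(out / "utrs.fa", self.utrs)
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        for sample_id in sorted(self.variants):
            write_vcf(vcf_dir / f"{sample_id}.vcf", self.variants[sample_id], self.genome, sample_id)
        with open(out / "snp_blacklist.tsv", "w") as fh:
            for chrom, pos, ref, alt in sorted(self.snp_blacklist):
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
        with open(out / "fingerprint_panel.tsv", "w") as fh:
            fh.write("#chrom\tpos\tref\talt\tmaf\n")
            for chrom, pos, ref, alt, maf in self.panel_snps:
                fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{maf:.4f}\n")
        with open(out / "fingerprint_depths.tsv", "w") as fh:
            fh.write("#pair_id\tmember\tsnp_index\tref_count\talt_count\n")
            for (pair, member), depths in sorted(self.fingerprint_depths.items()):
                for i, (rc, ac) in enumerate(depths):
                    fh.write(f"{pair}\t{member}\t{i}\t{rc}\t{ac}\n")
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        with open(truth_dir / "mutations.tsv", "w") as fh:
            cols = [f.name for f in dataclasses.fields(MutationTruth)]
            fh.write("\t".join(cols) + "\n")
            for mt in self.truth.mutations:
                fh.write("\t".join(str(getattr(mt, c)) for c in cols) + "\n")
        with open(truth_dir / "genes.tsv", "w") as fh:
            if self.truth.genes:
                cols = list(self.truth.genes[0])
                fh.write("\t".join(cols) + "\n")
                for row in self.truth.genes:
                    fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        with open(truth_dir / "swaps.tsv", "w") as fh:
            for pair in self.truth.swapped_pairs:
                fh.write(pair + "\n")
        with open(truth_dir / "utr_sites.tsv", "w") as fh:
            fh.write(f"#wt_seed={self.truth.wt_seed}\tmut_seed={self.truth.mut_seed}\n")
            for uid in sorted(self.truth.utr_sites):
                fh.write(f"{uid}\t{self.truth.utr_sites[uid]}\n")


# ---------------------------------------------------------------------------
# low-level writers


def write_fasta(path, records: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path, genes) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            p = g.precursor
            fh.write(
                f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start + 1}\t{p.end}\t.\t{p.strand}\t.\t"
                f"ID={g.gene_id};Name={g.name}\n"
            )
            for arm in ("5p", "3p"):
                iv = getattr(g, f"mature_{arm}")
                if iv is None:
                    continue
                fh.write(
                    f"{iv.chrom}\t.\tmiRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                    f"ID={g.gene_id}_{arm};Name={g.name}-{arm};Derives_from={g.gene_id}\n"
                )


def write_vcf(path, variants, genome: dict, sample_id: str) -> None:
    """Write tumor calls as an uncompressed VCF 4.2 with Mutect2-style
    fields: AF/AD in FORMAT, SEQQ/GERMQ/MBQ/MMQ in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genome:
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##INFO=<ID=SEQQ,Number=1,Type=Integer,Description="Phred quality that alt alleles are not sequencing errors">\n')
        fh.write('##INFO=<ID=GERMQ,Number=1,Type=Integer,Description="Phred quality that alt alleles are not germline variants">\n')
        fh.write('##INFO=<ID=MBQ,Number=1,Type=Integer,Description="Median base quality of alt reads">\n')
        fh.write('##INFO=<ID=MMQ,Number=1,Type=Integer,Description="Median mapping quality of alt reads">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            info = ";".join(
                f"{tag}={int(round(val))}"
                for tag, val in (
                    ("SEQQ", v.seqq), ("GERMQ", v.germq), ("MBQ", v.median_base_q), ("MMQ", v.median_map_q)
                )
                if val is not None
            ) or "."
            ad = f"{v.ref_count},{v.alt_count}" if v.ref_count is not None else "."
            af = f"{v.vaf:.4f}" if v.vaf is not None else "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\tGT:AD:AF\t0/1:{ad}:{af}\n"
            )


# ---------------------------------------------------------------------------
# generation helpers


def _random_seq(rng, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _place_genes(rng, config: SimulationConfig, chrom: str, genome_len: int):
    """Sample gene structures and non-overlapping placements."""
    occupied: list[tuple[int, int]] = []
    genes: list[MirnaGene] = []
    F = config.flank_len
    lo_p, hi_p = config.precursor_len_range
    lo_m, hi_m = config.mature_len_range
    min_loop = 10
    for i in range(config.n_genes):
        L = int(rng.integers(lo_p, hi_p + 1))
        m5 = int(rng.integers(lo_m, hi_m + 1))
        m3 = int(rng.integers(lo_m, min(hi_m, L - m5 - min_loop) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = False
        for _ in range(200):
            start = int(rng.integers(F + 10, genome_len - L - F - 10))
            span = (start - F - 5, start + L + F + 5)
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                occupied.append(span)
                placed = True
                break
        if not placed:
            raise GenerationError(
                "gene placement collision persisted; increase the genome size"
            )
        gene_id = f"MI-SYN-{i + 1:04d}"
        prec = GenomicInterval(chrom, start, start + L, strand)
        # arms flush with the precursor ends (duplex + loop fill the hairpin)
        if strand == "+":
            iv5 = GenomicInterval(chrom, start, start + m5, strand)
            iv3 = GenomicInterval(chrom, start + L - m3, start + L, strand)
        else:
            iv5 = GenomicInterval(chrom, start + L - m5, start + L, strand)
            iv3 = GenomicInterval(chrom, start, start + m3, strand)
        drop = rng.random()
        mature_5p, mature_3p = iv5, iv3
        if drop < config.single_arm_fraction / 2:
            mature_5p = None
        elif drop < config.single_arm_fraction:
            mature_3p = None
        genes.append(
            MirnaGene(
                gene_id=gene_id,
                name=f"mir-syn-{i + 1}",
                precursor=prec,
                mature_5p=mature_5p,
                mature_3p=mature_3p,
                flank_len=F,
                confidence="high",
            )
        )
    return genes


def _draw_vaf(rng, config: SimulationConfig, below_cut: bool) -> float:
    a, b = config.vaf_beta
    if below_cut:
        return float(rng.uniform(0.005, config.min_vaf - 0.005))
    for _ in range(1000):
        v = float(rng.beta(a, b))
        if v >= config.min_vaf:
            return v
    return config.min_vaf


def _qualities(rng, low_quality: bool):
    """(mbq, mmq, seqq, germq); one random field degraded if requested."""
    q = {
        "mbq": int(rng.integers(25, 41)),
        "mmq": int(rng.integers(40, 61)),
        "seqq": int(rng.integers(30, 94)),
        "germq": int(rng.integers(30, 94)),
    }
    if low_quality:
        which = ("mbq", "mmq", "seqq", "germq")[int(rng.integers(0, 4))]
        q[which] = int(rng.integers(2, 20)) if which != "mmq" else int(rng.integers(5, 30))
    return q


def _depths(rng, config: SimulationConfig, vaf: float):
    depth = max(50, int(rng.poisson(config.sequencing_depth)))
    alt = int(round(vaf * depth))
    alt = max(1, min(depth - 1, alt))
    return depth - alt, alt, alt / depth


def _alt_base(rng, ref: str) -> str:
    choices = [b for b in BASES if b != ref]
    return choices[int(rng.integers(0, 3))]


class _MutationFactory:
    """Builds VCF-convention records for planted events on either strand."""

    def __init__(self, rng, genome: dict, config: SimulationConfig):
        self.rng = rng
        self.genome = genome
        self.config = config

    def _base(self, chrom: str, pos: int) -> str:
        return self.genome[chrom][pos - 1]

    def build(self, gene: MirnaGene, signed_pos: int, mtype: str):
        """Return (pos, ref, alt, affected_signed_ok) or None if the event
        would run outside the targeted span (caller falls back or skips)."""
        chrom = gene.precursor.chrom
        g = precursor_to_genomic(gene, signed_pos)
        rng = self.rng
        L, F = gene.precursor_len, gene.flank_len

        def in_target(signed):
            return -F <= signed <= L + F and signed != 0

        if mtype == "substitution":
            ref = self._base(chrom, g)
            return g, ref, _alt_base(rng, ref), [g]

        if mtype == "dinucleotide_substitution":
            nxt = signed_pos + 1 if signed_pos != -1 else 1
            if not in_target(nxt):
                return None
            g2 = precursor_to_genomic(gene, nxt)
            lo = min(g, g2)
            ref = self.genome[chrom][lo - 1 : lo + 1]
            alt = _alt_base(rng, ref[0]) + _alt_base(rng, ref[1])
            return lo, ref, alt, [lo, lo + 1]

        if mtype == "deletion":
            dl = int(rng.integers(1, 4))
            signed_del = []
            s = signed_pos
            for _ in range(dl):
                if not in_target(s):
                    return None
                signed_del.append(s)
                s = s + 1 if s != -1 else 1
            gpos = sorted(precursor_to_genomic(gene, p) for p in signed_del)
            anchor = gpos[0] - 1
            if anchor < 1 or not in_target_genomic(gene, anchor):
                return None
            ref = self.genome[chrom][anchor - 1 : gpos[-1]]
            return anchor, ref, ref[0], gpos

        if mtype == "insertion":
            nxt = signed_pos + 1 if signed_pos != -1 else 1
            if not in_target(nxt):
                return None
            il = int(rng.integers(1, 4))
            ins = _random_seq(rng, il)
            g2 = precursor_to_genomic(gene, nxt)
            anchor = min(g, g2)
            ref = self._base(chrom, anchor)
            return anchor, ref, ref + ins, [anchor, anchor + 1]

        raise ValueError(mtype)


# ---------------------------------------------------------------------------
# UTR planting


def _site_patterns(seed: str) -> tuple[str, str]:
    """(7mer-m8 core, 7mer-A1 heptamer) DNA patterns of a seed."""
    s = seed.upper().replace("U", "T")
    return revcomp(s), revcomp(s[:6]) + "A"


def _scrub(rng, seq: str, patterns) -> str:
    """Destroy every occurrence of any pattern by point-changing its middle."""
    seq = list(seq)
    for _ in range(100):
        text = "".join(seq)
        hit = None
        for pat in patterns:
            i = text.find(pat)
            if i != -1:
                hit = (i, pat)
                break
        if hit is None:
            return text
        i, pat = hit
        j = i + len(pat) // 2
        seq[j] = _alt_base(rng, seq[j])
    raise GenerationError("UTR scrubbing did not converge")


def _plant_utrs(rng, config: SimulationConfig, wt_seed: str, mut_seed: str):
    wt_m8, wt_a1 = _site_patterns(wt_seed)
    mut_m8, mut_a1 = _site_patterns(mut_seed)
    all_patterns = (wt_m8, wt_a1, mut_m8, mut_a1)
    n_wt, n_sh, n_mut = config.planted_site_counts
    if n_wt + n_sh + n_mut > config.n_utrs:
        raise ValueError("planted_site_counts exceed n_utrs")
    classes = ["wt_only"] * n_wt + ["shared"] * n_sh + ["mut_only"] * n_mut
    classes += ["none"] * (config.n_utrs - len(classes))

    utrs: dict[str, str] = {}
    memberships: dict[str, str] = {}
    for i, cls in enumerate(classes):
        uid = f"UTR{i + 1:04d}"
        for _attempt in range(50):
            seq = _scrub(rng, _random_seq(rng, config.utr_len), all_patterns)
            inserts = []
            if cls in ("wt_only", "shared"):
                inserts.append(wt_m8 + "A")
            if cls in ("mut_only", "shared"):
                inserts.append(mut_m8 + "A")
            ok = True
            for ins in inserts:
                pos = int(rng.integers(10, config.utr_len - 10 - len(ins)))
                seq = seq[:pos] + ins + seq[pos + len(ins):]
            # inserting one site must not have created a site of the other seed
            want_wt = cls in ("wt_only", "shared")
            want_mut = cls in ("mut_only", "shared")
            has_wt = wt_m8 in seq or wt_a1 in seq
            has_mut = mut_m8 in seq or mut_a1 in seq
            ok = (has_wt == want_wt) and (has_mut == want_mut)
            if ok:
                utrs[uid] = seq
                memberships[uid] = cls
                break
        else:
            raise GenerationError(f"could not construct UTR of class {cls}")
    return utrs, memberships


# ---------------------------------------------------------------------------
# main entry


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given ``rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    truth = SyntheticTruth()

    chrom = "chr1"
    genome_len = max(20_000, config.n_genes * 400)
    genome = {chrom: _random_seq(rng, genome_len)}

    genes = _place_genes(rng, config, chrom, genome_len)
    for g in genes:
        row = {
            "gene_id": g.gene_id,
            "name": g.name,
            "chrom": g.precursor.chrom,
            "start": g.precursor.start,
            "end": g.precursor.end,
            "strand": g.strand,
            "flank_len": g.flank_len,
        }
        for arm in ("5p", "3p"):
            iv = getattr(g, f"mature_{arm}")
            row[f"mature_{arm}"] = f"{iv.start}-{iv.end}" if iv else ""
        truth.genes.append(row)

    subregions = {g.gene_id: derive_subregions(g, on_short_arm="duplex") for g in genes}
    base_spans = {
        gid: [r for r in regs if not r.overlay] for gid, regs in subregions.items()
    }

    # ---- common-SNP blacklist sites inside genes
    blacklist = set()
    bl_sites = []
    for _ in range(config.n_blacklist_sites):
        g = genes[int(rng.integers(0, len(genes)))]
        span = g.target_span
        pos = int(rng.integers(span.start + 1, span.end + 1))
        ref = genome[chrom][pos - 1]
        alt = _alt_base(rng, ref)
        if (chrom, pos, ref, alt) not in blacklist:
            blacklist.add((chrom, pos, ref, alt))
            bl_sites.append((pos, ref, alt))

    factory = _MutationFactory(rng, genome, config)
    type_names = ("substitution", "deletion", "insertion", "dinucleotide_substitution")
    type_p = np.asarray(config.mutation_type_probs, dtype=float)
    type_p = type_p / type_p.sum()

    variants: dict[str, list[Variant]] = {}
    pair_ids = [f"P{i + 1:03d}" for i in range(config.n_sample_pairs)]

    used_by_sample: dict[str, set[int]] = {}

    def plant(sample_id, pair_id, gene, signed_pos, mtype, *, below_cut=False,
              low_quality=False, forced=None):
        """Build one record; returns True if planted."""
        if forced is None:
            built = factory.build(gene, signed_pos, mtype)
            if built is None and mtype != "substitution":
                mtype = "substitution"
                built = factory.build(gene, signed_pos, mtype)
            if built is None:
                return False
            pos, ref, alt, affected = built
        else:
            pos, ref, alt = forced
            mtype = "substitution"
            affected = [pos]
        footprint = range(pos, pos + len(ref))
        used = used_by_sample.setdefault(sample_id, set())
        if any(p in used for p in footprint):
            return False
        used.update(footprint)
        should_pass = not (below_cut or low_quality or forced is not None)
        vaf = _draw_vaf(rng, config, below_cut)
        q = _qualities(rng, low_quality)
        rc, ac, vaf_obs = _depths(rng, config, vaf)
        if should_pass and vaf_obs < config.min_vaf:
            depth = rc + ac
            ac = int(np.ceil(config.min_vaf * depth))
            rc = depth - ac
            vaf_obs = ac / depth
        v = Variant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, sample_id=sample_id,
            vaf=vaf_obs, ref_count=rc, alt_count=ac,
            seqq=q["seqq"], germq=q["germq"],
            median_base_q=q["mbq"], median_map_q=q["mmq"],
        )
        variants.setdefault(sample_id, []).append(v)
        fail = "low_vaf" if below_cut else ("low_quality" if low_quality else
                                            ("common_snp" if forced is not None else ""))
        # truth label from the 5'-most affected precursor position
        signed_affected = [s for p in affected if (s := _safe_signed(gene, p)) is not None]
        truth_signed = min(signed_affected)
        sub = label_position(subregions[gene.gene_id], truth_signed)
        truth.mutations.append(
            MutationTruth(
                sample_id=sample_id, pair_id=pair_id, chrom=chrom, pos=pos,
                ref=ref, alt=alt, gene_id=gene.gene_id, signed_pos=truth_signed,
                subregion=sub.label, weight=sub.weight, vaf=vaf_obs,
                mutation_type=mtype, should_pass_filters=should_pass, fail_reason=fail,
            )
        )
        return True

    n_pass_planted = 0
    for pair_id in pair_ids:
        sample_id = f"{pair_id}_T"
        variants.setdefault(sample_id, [])
        for gene in genes:
            for region in base_spans[gene.gene_id]:
                rate = config.per_subregion_rates.get(region.label, 0.0)
                lam = rate * len(region) / 1e6
                n = int(rng.poisson(lam))
                positions = _region_positions(region)
                for _ in range(n):
                    mtype = type_names[int(rng.choice(4, p=type_p))]
                    for _try in range(10):
                        signed_pos = positions[int(rng.integers(0, len(positions)))]
                        if plant(sample_id, pair_id, gene, signed_pos, mtype):
                            n_pass_planted += 1
                            break

    # ---- filter-violating decoys, spread over random samples/genes
    def spread_decoys(n, **kwargs):
        for _ in range(n):
            pair_id = pair_ids[int(rng.integers(0, len(pair_ids)))]
            sample_id = f"{pair_id}_T"
            gene = genes[int(rng.integers(0, len(genes)))]
            regs = base_spans[gene.gene_id]
            region = regs[int(rng.integers(0, len(regs)))]
            positions = _region_positions(region)
            signed_pos = positions[int(rng.integers(0, len(positions)))]
            plant(sample_id, pair_id, gene, signed_pos, "substitution", **kwargs)

    spread_decoys(int(round(config.fraction_below_vaf_cut * n_pass_planted)), below_cut=True)
    spread_decoys(int(round(config.fraction_low_quality * n_pass_planted)), low_quality=True)
    n_snp_decoys = int(round(config.fraction_common_snp * n_pass_planted))
    if bl_sites:
        gene_by_pos = _gene_lookup(genes)
        for _ in range(n_snp_decoys):
            pair_id = pair_ids[int(rng.integers(0, len(pair_ids)))]
            pos, ref, alt = bl_sites[int(rng.integers(0, len(bl_sites)))]
            gene = gene_by_pos(pos)
            if gene is not None:
                plant(f"{pair_id}_T", pair_id, gene, 0, "substitution", forced=(pos, ref, alt))

    # ---- fingerprint panel and genotypes
    fp_chrom = "chrFP"
    fp_len = config.n_snp_panel * 50 + 200
    genome[fp_chrom] = _random_seq(rng, fp_len)
    panel = []
    for i in range(config.n_snp_panel):
        pos = 100 + i * 50
        ref = genome[fp_chrom][pos - 1]
        alt = _alt_base(rng, ref)
        maf = float(rng.uniform(*config.snp_maf_range))
        panel.append((fp_chrom, pos, ref, alt, maf))

    swapped = sorted(
        rng.choice(len(pair_ids), size=min(config.n_swapped_pairs, len(pair_ids)), replace=False).tolist()
    )
    truth.swapped_pairs = [pair_ids[i] for i in swapped]
    depths: dict[tuple[str, str], list[tuple[int, int]]] = {}

    def draw_genotype_dosages():
        return [int(rng.binomial(2, maf)) for (_, _, _, _, maf) in panel]

    def dosage_depths(dosages):
        out = []
        for d in dosages:
            frac = (0.002, 0.5, 0.998)[d]
            total = 100
            alt_n = int(rng.binomial(total, frac))
            out.append((total - alt_n, alt_n))
        return out

    for idx, pair_id in enumerate(pair_ids):
        normal = draw_genotype_dosages()
        tumor = draw_genotype_dosages() if idx in swapped else list(normal)
        depths[(pair_id, "N")] = dosage_depths(normal)
        depths[(pair_id, "T")] = dosage_depths(tumor)

    # ---- UTR database with planted seed-match sites
    guide_gene = next(g for g in genes if g.mature_5p is not None)
    arm5 = guide_gene.arm_span_rel("5p")
    mature_seq = _gene_strand_seq(genome, guide_gene, arm5)
    wt_seed = mature_seq[1:8]
    mut_idx = 3  # seed position 4 (mature nt 5)
    mut_seed = wt_seed[:mut_idx] + _alt_base(rng, wt_seed[mut_idx]) + wt_seed[mut_idx + 1:]
    utrs, memberships = _plant_utrs(rng, config, wt_seed, mut_seed)
    truth.wt_seed, truth.mut_seed = wt_seed, mut_seed
    truth.utr_sites = memberships

    return SimulatedCohort(
        config=config,
        genome=genome,
        genes=genes,
        variants=variants,
        snp_blacklist=frozenset(blacklist),
        panel_snps=panel,
        fingerprint_depths=depths,
        utrs=utrs,
        truth=truth,
    )


def _region_positions(region) -> list:
    return [p for p in range(region.start, region.end + 1) if p != 0]


def _safe_signed(gene, genomic_pos):
    from .genemodel import OutOfTargetError

    try:
        return genomic_to_signed(gene, genomic_pos)
    except OutOfTargetError:
        return None


def in_target_genomic(gene, genomic_pos) -> bool:
    return _safe_signed(gene, genomic_pos) is not None


def _gene_lookup(genes):
    spans = [(g.target_span.start, g.target_span.end, g) for g in genes]

    def lookup(pos_1based):
        p0 = pos_1based - 1
        for s, e, g in spans:
            if s <= p0 < e:
                return g
        return None

    return lookup


def _gene_strand_seq(genome, gene, rel_span) -> str:
    s, e = rel_span
    if gene.strand == "+":
        start0 = gene.precursor.start + s - 1
        return genome[gene.precursor.chrom][start0 : start0 + (e - s + 1)]
    end0 = gene.precursor.end - s + 1
    return revcomp(genome[gene.precursor.chrom][end0 - (e - s + 1) : end0])
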