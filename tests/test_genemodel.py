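"""Gene coordinate model: GFF3 loading, subregion tiling, coordinate maps."""

import pytest

from conftest import TEST_SEED, make_gene
from mirnome.genemodel import (
    AnnotationError,
    GFF3ParseError,
    GenomicInterval,
    MirnaGene,
    OutOfTargetError,
    SeedTruncationError,
    anchor_offset_to_signed,
    derive_subregions,
    genomic_to_precursor,
    genomic_to_signed,
    label_position,
    load_gene_annotations,
    precursor_to_genomic,
    signed_to_anchor_offset,
    subregion_weight,
)
from mirnome.simulate import SimulationConfig, simulate_cohort, write_gff3

GFF_OK = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t1001\t1060\t.\t+\t.\tID=MI001;Name=mir-a
chr1\t.\tmiRNA\t1001\t1022\t.\t+\t.\tID=MAT1;Name=mir-a-5p;Derives_from=MI001
chr1\t.\tmiRNA\t1039\t1060\t.\t+\t.\tID=MAT2;Name=mir-a-3p;Derives_from=MI001
"""

GFF_MINUS_ONE_ARM = """##gff-version 3
chr2\t.\tmiRNA_primary_transcript\t501\t580\t.\t-\t.\tID=MI002;Name=mir-b
chr2\t.\tmiRNA\t559\t580\t.\t-\t.\tID=MAT3;Name=mir-b-5p;Derives_from=MI002
"""


class TestGff3Loading:
    def test_two_arm_plus_strand(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_OK)
        (gene,) = load_gene_annotations(str(p))
        assert gene.gene_id == "MI001"
        assert gene.mature_5p is not None and gene.mature_3p is not None
        assert gene.precursor.start == 1000 and gene.precursor.end == 1060
        assert gene.confidence == "high"

    def test_minus_strand_single_arm(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(GFF_MINUS_ONE_ARM)
        (gene,) = load_gene_annotations(str(p))
        # on the minus strand the 5p arm sits at the higher genomic coordinates
        assert gene.mature_5p is not None and gene.mature_3p is None
        assert gene.arm_span_rel("5p") == (1, 22)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text(GFF_OK + "chr1\tonly\tthree\n")
        with pytest.raises(GFF3ParseError, match="line 5"):
            load_gene_annotations(str(p))

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad2.gff3"
        p.write_text("chr1\t.\tmiRNA_primary_transcript\txx\t50\t.\t+\t.\tID=M\n")
        with pytest.raises(GFF3ParseError, match="line 1"):
            load_gene_annotations(str(p))

    def test_duplicate_precursor_id_rejected(self, tmp_path):
        p = tmp_path / "dup.gff3"
        p.write_text(GFF_OK + GFF_OK.splitlines()[1] + "\n")
        with pytest.raises(AnnotationError, match="duplicate"):
            load_gene_annotations(str(p))

    def test_mature_outside_parent_rejected(self, tmp_path):
        p = tmp_path / "nest.gff3"
        p.write_text(
            "chr1\t.\tmiRNA_primary_transcript\t1001\t1060\t.\t+\t.\tID=MI001;Name=m\n"
            "chr1\t.\tmiRNA\t2000\t2021\t.\t+\t.\tID=MAT;Name=m-5p;Derives_from=MI001\n"
        )
        with pytest.raises(AnnotationError, match="not nested"):
            load_gene_annotations(str(p))

    def test_precursor_without_mature_flagged_low_confidence(self, tmp_path):
        p = tmp_path / "lone.gff3"
        p.write_text("chr1\t.\tmiRNA_primary_transcript\t1001\t1060\t.\t+\t.\tID=MI001;Name=m\n")
        (gene,) = load_gene_annotations(str(p))
        assert gene.confidence == "low"

    def test_synthetic_round_trip_recovers_planted_coordinates(self, tmp_path):
        cohort = simulate_cohort(SimulationConfig(rng_seed=TEST_SEED, n_genes=50))
        path = tmp_path / "syn.gff3"
        write_gff3(path, cohort.genes)
        loaded = {g.gene_id: g for g in load_gene_annotations(str(path))}
        assert len(loaded) == 50
        for row in cohort.truth.genes:
            g = loaded[row["gene_id"]]
            assert (g.precursor.start, g.precursor.end, g.strand) == (
                row["start"], row["end"], row["strand"],
            )
            for arm in ("5p", "3p"):
                iv = getattr(g, f"mature_{arm}")
                expected = row[f"mature_{arm}"]
                got = f"{iv.start}-{iv.end}" if iv else ""
                assert got == expected


class TestSubregions:
    def test_seed_is_mature_nt_2_to_8(self, plus_gene):
        regions = derive_subregions(plus_gene)
        seed5 = next(r for r in regions if r.label == "seed" and r.start < 30)
        # 5p arm starts at precursor position 1 -> seed = positions 2-8
        assert (seed5.start, seed5.end) == (2, 8)
        assert seed5.weight == 2.0

    def test_loop_is_gap_between_arms(self):
        gene = make_gene(precursor_len=54, m5=22, m3=22)  # 10 nt loop
        regions = derive_subregions(gene)
        loop = next(r for r in regions if r.label == "loop")
        assert (loop.start, loop.end) == (23, 32)
        assert len(loop) == 10

    def test_short_mature_arm_raises(self):
        gene = make_gene(precursor_len=60, m5=7, m3=22)
        with pytest.raises(SeedTruncationError):
            derive_subregions(gene)

    def test_tiling_partitions_target_exactly(self, default_cohort):
        """Non-overlay subregions tile [-F .. L+F] with no gaps or overlaps."""
        for gene in default_cohort.genes:
            regions = [r for r in derive_subregions(gene, on_short_arm="duplex") if not r.overlay]
            F, L = gene.flank_len, gene.precursor_len
            axis = [p for p in range(-F, L + F + 1) if p != 0]
            assert sum(len(r) for r in regions) == len(axis) == gene.target_len
            for p in axis:
                assert sum(r.covers(p) for r in regions) == 1, (gene.gene_id, p)

    def test_passenger_inference_single_arm(self):
        gene = make_gene(precursor_len=60, single_arm="5p")
        regions = derive_subregions(gene)
        passenger = [r for r in regions if r.label == "passenger_arm_part"]
        assert len(passenger) == 1
        # mirrored across the hairpin with a 2-nt 3' overhang
        (p,) = passenger
        assert p.end == 60 - 2  # L + 1 - a1 - overhang with a1 = 1
        assert p.weight == 1.5

    def test_cleavage_overlay_straddles_duplex_ends(self, plus_gene):
        regions = derive_subregions(plus_gene)
        cleav = sorted({(r.start, r.end) for r in regions if r.label == "cleavage_site"})
        # arms at 1-22 and 39-60 (L=60): scissile phosphates at both ends of each arm
        assert (22, 23) in cleav and (38, 39) in cleav
        # seed outranks a cleavage overlay; cleavage outranks loop/duplex
        assert label_position(regions, 23).label == "cleavage_site"
        assert label_position(regions, 2).label == "seed"

    def test_weight_mapping(self):
        assert subregion_weight("seed", guide=True) == 2.0
        assert subregion_weight("seed", guide=False) == 1.0
        assert subregion_weight("loop") == 1.0
        for label in ("preseed", "postseed", "passenger_arm_part", "cleavage_site", "protein_motif"):
            assert subregion_weight(label) == 1.5

    def test_dominant_arm_restricts_seed_weighting(self, plus_gene):
        regions = derive_subregions(plus_gene, guide_arms=["5p"])
        labels_3p = {r.label for r in regions if 39 <= r.start <= 60 and not r.overlay}
        assert labels_3p == {"passenger_arm_part"}

    def test_strand_symmetry_of_labels(self):
        """A gene and its reverse-complement mirror produce identical
        precursor-relative subregion labels."""
        plus = make_gene("+", precursor_len=64, m5=20, m3=21)
        minus = make_gene("-", precursor_len=64, m5=20, m3=21)
        lp = {p: label_position(derive_subregions(plus), p).label
              for p in range(-25, 90) if p != 0}
        lm = {p: label_position(derive_subregions(minus), p).label
              for p in range(-25, 90) if p != 0}
        assert lp == lm


class TestCoordinates:
    def test_upstream_flank_position(self, plus_gene):
        # 16 nt upstream of the precursor start
        g = plus_gene.precursor.start + 1 - 16  # 1-based genomic
        assert genomic_to_precursor(plus_gene, g) == (1, -16)

    def test_precursor_start_is_position_one(self, plus_gene):
        assert genomic_to_precursor(plus_gene, plus_gene.precursor.start + 1) == (1, 0)

    def test_downstream_flank(self, plus_gene):
        L = plus_gene.precursor_len
        g = plus_gene.precursor.end + 3
        assert genomic_to_precursor(plus_gene, g) == (L, 3)

    def test_out_of_target_raises(self, plus_gene):
        with pytest.raises(OutOfTargetError):
            genomic_to_precursor(plus_gene, plus_gene.precursor.start - 26)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bijection_on_both_strands(self, strand):
        gene = make_gene(strand, precursor_len=73, m5=19, m3=23)
        F, L = gene.flank_len, gene.precursor_len
        seen = set()
        for signed in [p for p in range(-F, L + F + 1) if p != 0]:
            g = precursor_to_genomic(gene, signed)
            assert genomic_to_signed(gene, g) == signed
            seen.add(g)
        span = gene.target_span
        assert seen == set(range(span.start + 1, span.end + 1))

    def test_anchor_offset_round_trip(self):
        L = 60
        for signed in [-25, -1, 1, 30, 60, 61, 85]:
            anchor, offset = signed_to_anchor_offset(signed, L)
            assert anchor_offset_to_signed(anchor, offset, L) == signed
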