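"""Variant annotation: mutation typing, HGVS n. strings, subregion labels."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_gene
from mirnome.annotate import (
    AnnotatedVariant,
    GeneIndex,
    NormalizationError,
    Variant,
    annotate_cohort,
    annotate_variant,
    classify_mutation_type,
    hgvs_n,
    mirmut_weight,
    normalize_alleles,
    parse_hgvs_n,
    revcomp,
)
from mirnome.genemodel import signed_to_anchor_offset


def brute_force_classify(ref: str, alt: str) -> str:
    """Independent classifier written straight from the definitions:
    trim shared suffix then prefix, then compare residual lengths."""
    r, a = list(ref), list(alt)
    while r and a and r[-1] == a[-1]:
        r.pop(), a.pop()
    while r and a and r[0] == a[0]:
        r.pop(0), a.pop(0)
    if not r and not a:
        raise NormalizationError("identical")
    if len(r) == 1 and len(a) == 1:
        return "substitution"
    if len(r) == 2 and len(a) == 2 and r[0] != a[0] and r[1] != a[1]:
        return "dinucleotide_substitution"
    if len(a) > len(r) == 0:
        return "insertion"
    if len(r) > len(a) == 0:
        return "deletion"
    return "complex"


class TestMutationType:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("G", "A", "substitution"),
            ("CT", "AG", "dinucleotide_substitution"),
            ("A", "AT", "insertion"),
            ("AT", "A", "deletion"),
            ("ACG", "A", "deletion"),
            ("ACG", "TGA", "complex"),
            ("CAT", "CGT", "substitution"),  # trims to A>G
        ],
    )
    def test_examples(self, ref, alt, expected):
        assert classify_mutation_type(ref, alt) == expected

    def test_identical_after_trim_raises(self):
        with pytest.raises(NormalizationError):
            classify_mutation_type("ACA", "ACA")

    def test_exhaustive_agreement_with_brute_force(self):
        """Every allele pair up to length 3 classifies identically to an
        independent from-the-definitions classifier."""
        alphabet = "ACGT"
        alleles = [
            "".join(t) for n in (1, 2, 3) for t in itertools.product(alphabet, repeat=n)
        ]
        checked = 0
        for ref, alt in itertools.product(alleles, repeat=2):
            try:
                expected = brute_force_classify(ref, alt)
            except NormalizationError:
                with pytest.raises(NormalizationError):
                    classify_mutation_type(ref, alt)
                continue
            assert classify_mutation_type(ref, alt) == expected, (ref, alt)
            checked += 1
        assert checked > 6000

    def test_normalize_shifts_position(self):
        assert normalize_alleles("CAT", "CGT", pos=10) == (11, "A", "G")
        assert normalize_alleles("ATT", "A", pos=10) == (11, "TT", "")


class TestHgvs:
    @pytest.mark.parametrize(
        "coord,ref,alt,expected",
        [
            ((1, -16), "G", "A", "n.1-16G>A"),
            ((45, 0), "G", "A", "n.45G>A"),
            ((41, 0), "G", "T", "n.41G>T"),
            ((60, 3), "C", "T", "n.60+3C>T"),
        ],
    )
    def test_substitution_rendering(self, coord, ref, alt, expected):
        assert hgvs_n(coord, ref, alt, "substitution") == expected

    def test_multi_nucleotide_rendering(self):
        assert hgvs_n(((5, 0), (7, 0)), "ACT", "", "deletion") == "n.5_7delACT"
        assert hgvs_n(((5, 0), (5, 0)), "A", "", "deletion") == "n.5delA"
        assert hgvs_n(((5, 0), (6, 0)), "", "GG", "insertion") == "n.5_6insGG"
        assert hgvs_n(((5, 0), (6, 0)), "CT", "AG", "dinucleotide_substitution") == "n.5_6delCTinsAG"

    @settings(derandomize=True, max_examples=300)
    @given(
        anchor=st.integers(1, 80),
        offset=st.sampled_from([-20, -16, 0, 0, 0]),
        ref=st.text("ACGT", min_size=1, max_size=3),
        alt=st.text("ACGT", min_size=1, max_size=3),
    )
    def test_round_trip(self, anchor, offset, ref, alt):
        """Parsing an emitted string recovers (coord, ref, alt) exactly."""
        if ref == alt:
            return
        try:
            _, r, a = normalize_alleles(ref, alt)
        except NormalizationError:
            return
        mtype = classify_mutation_type(ref, alt)
        L = 1000
        start_signed = offset if offset < 0 else anchor
        span = max(len(r), 1) + (1 if mtype == "insertion" else 0)
        end_signed = start_signed + span - 1
        if start_signed < 0 <= end_signed:
            end_signed += 1
        start = signed_to_anchor_offset(start_signed, L)
        end = signed_to_anchor_offset(end_signed, L)
        if mtype == "substitution":
            s = hgvs_n(start, r, a, mtype)
        else:
            s = hgvs_n((start, end), r, a, mtype)
        p_start, p_end, p_ref, p_alt, p_type = parse_hgvs_n(s)
        assert (p_start, p_ref, p_alt, p_type) == (start, r, a, mtype)
        if mtype != "substitution":
            assert p_end == end


def build_index(*genes):
    return GeneIndex(genes)


class TestAnnotation:
    def test_plus_strand_substitution(self, plus_gene):
        g = plus_gene.precursor.start + 45  # precursor position 45
        v = Variant("chr1", g, "G", "A", sample_id="S1", vaf=0.3)
        (av,) = annotate_variant(v, build_index(plus_gene))
        assert av.hgvs_n == "n.45G>A"
        assert av.precursor_coord == (45, 0)

    def test_minus_strand_alleles_complemented(self, minus_gene):
        # genomic C>T inside a minus-strand gene reports as G>A
        g = minus_gene.precursor.end - 10  # precursor position 11
        v = Variant("chr1", g, "C", "T", sample_id="S1", vaf=0.3)
        (av,) = annotate_variant(v, build_index(minus_gene))
        assert av.hgvs_n.endswith("G>A")
        assert av.precursor_coord == (11, 0)

    def test_variant_in_two_clustered_genes_yields_two_records(self):
        a = make_gene("+", start=1000, gene_id="MI-A")
        b = make_gene("-", start=1030, gene_id="MI-B")
        v = Variant("chr1", 1040, "A", "G", sample_id="S1", vaf=0.2)
        records = annotate_variant(v, build_index(a, b))
        assert sorted(r.gene_id for r in records) == ["MI-A", "MI-B"]

    def test_no_overlap_returns_empty(self, plus_gene):
        v = Variant("chr1", 5, "A", "G", vaf=0.2)
        assert annotate_variant(v, build_index(plus_gene)) == []

    def test_upstream_flank_substitution(self, plus_gene):
        g = plus_gene.precursor.start + 1 - 16
        v = Variant("chr1", g, "G", "A", vaf=0.2)
        (av,) = annotate_variant(v, build_index(plus_gene))
        assert av.hgvs_n == "n.1-16G>A"
        assert av.subregion_label == "flank5"
        assert av.weight == 1.0

    def test_seed_variant_gets_weight_two(self, plus_gene):
        g = plus_gene.precursor.start + 4  # precursor position 4: seed (nt 2-8)
        v = Variant("chr1", g, "A", "C", vaf=0.2)
        (av,) = annotate_variant(v, build_index(plus_gene))
        assert av.subregion_label == "seed"
        assert av.weight == 2.0 == mirmut_weight("seed", True)
        assert av.arm == "5p" and av.within_mature_pos == 4

    def test_weight_always_matches_label(self, default_cohort):
        """No orphan weights: every record's weight re-derives from its label."""
        index = GeneIndex(default_cohort.genes)
        allv = [v for vs in default_cohort.variants.values() for v in vs]
        for av in annotate_cohort(allv, index):
            guide = av.subregion_label == "seed"
            assert av.weight == mirmut_weight(av.subregion_label, guide)

    def test_annotation_order_independent(self, default_cohort):
        index = GeneIndex(default_cohort.genes)
        allv = [v for vs in default_cohort.variants.values() for v in vs]
        fwd = annotate_cohort(allv, index)
        rev = annotate_cohort(list(reversed(allv)), index)
        key = lambda a: (a.variant.sample_id, a.variant.chrom, a.variant.pos, a.gene_id, a.hgvs_n)
        assert [key(a) for a in fwd] == [key(a) for a in rev]

    def test_boundary_spanning_deletion_flagged(self, plus_gene):
        # deletion starting 2 nt inside the upstream flank edge, running out
        g = plus_gene.precursor.start + 1 - 26  # one nt outside target
        ref = "AAAA"
        v = Variant("chr1", g, ref, "A", vaf=0.2)
        (av,) = annotate_variant(v, build_index(plus_gene))
        assert av.boundary_warning
        assert av.mutation_type == "deletion"

    def test_planted_truth_recovery(self, default_cohort):
        """Every planted mutation recovers its planted gene, subregion, weight."""
        index = GeneIndex(default_cohort.genes)
        truth = {
            (mt.sample_id, mt.pos, mt.ref, mt.alt): mt
            for mt in default_cohort.truth.mutations
        }
        allv = [v for vs in default_cohort.variants.values() for v in vs]
        annotated = annotate_cohort(allv, index)
        assert len(annotated) == len(truth)
        for av in annotated:
            v = av.variant
            mt = truth[(v.sample_id, v.pos, v.ref, v.alt)]
            assert (av.gene_id, av.subregion_label, av.weight) == (
                mt.gene_id, mt.subregion, mt.weight,
            )
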