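# Methods

## Gene coordinate model

A miRNA gene is modeled as the annotated hairpin precursor plus fixed
flanks. The default flank is 25 nt; it is a constructor argument
everywhere (`flank_len`). All internal genomic intervals are 0-based
half-open; everything rendered for humans (HGVS, reports) is 1-based
inclusive. Precursor-relative positions live on a signed axis with no
zero: `-F..-1` upstream flank, `1..L` precursor, `L+1..L+F` downstream
flank, rendered HGVS-style as `1-k`, `n`, and `L+k`.

Functional subregions tile this axis exactly:

- `flank5` / `flank3` — the flanks, plus any precursor positions outside
  the duplex and loop (lower stem). Hairpins whose annotated arms are not
  flush with the precursor ends have such positions; folding them into the
  flank labels keeps the tiling gap-free with a small label vocabulary,
  and their weight (1×) is the same either way.
- guide arms are split into `preseed` (mature nt 1), `seed` (nt 2–8),
  `postseed` (nt 9..end); an arm shorter than 8 nt raises a seed
  truncation error by default (`on_short_arm="duplex"` downgrades it to
  an undivided duplex block instead of silently clipping).
- `passenger_arm_part` — a non-guide arm. When only one arm is annotated,
  the passenger is inferred by mirroring the guide across the hairpin
  (position p pairs with L+1−p) shifted by a configurable 2-nt 3′
  overhang, the geometry DROSHA/DICER1 processing leaves on the duplex.
- `loop` — the span between the arms.

DROSHA and DICER1 cleavage sites and user-supplied protein-binding motifs
are *overlays*: they do not participate in the tiling but take precedence
when labeling a position. The cleavage window defaults to 2 nt centered
on each scissile phosphate (the four duplex ends); no consensus window
width exists in the literature, so it is configurable. The motif catalog
defaults to empty and is supplied as precursor-relative spans per gene.

Label precedence at a position is highest-weight-first, with ties broken
seed > cleavage site > motif > duplex > loop/flank.

Guide-strand policy: every annotated arm counts as a guide by default
(both arms of a two-arm gene carry 2× seeds); `guide_arms=["5p"]`
restricts seed weighting to a dominant arm. An inferred passenger arm is
never a guide.

## miRMut weights and per-gene score

Weights: seed on a guide arm 2.0; duplex, cleavage site, motif 1.5;
everything else 1.0. A seed label on a non-guide arm weighs 1.0 by the
weight function's contract, but the annotation path labels those
positions `passenger_arm_part` (1.5, duplex) instead. The per-gene score
is the plain sum of its mutations' weights, so n ≤ score ≤ 2n always.

## Variant annotation

Alleles are normalized by trimming the shared suffix then prefix
(left-aligned, VCF convention), which makes the mutation-type
classification well defined: 1→1 substitution, 2→2 dinucleotide
substitution, pure gain insertion, pure loss deletion, otherwise complex.
A variant is annotated once per overlapping gene (clustered genes yield
multiple records); alleles are reported on the gene strand. Indels are
assigned the subregion of their 5′-most affected precursor position
(configurable to highest-weight-overlapped); indels running over the
target boundary are annotated to the overlapping part and flagged.

HGVS `n.` strings state deleted/replaced residues explicitly
(`n.5_7delACT`, `n.5_6delCTinsAG`) so that parsing an emitted string
recovers coordinates and both alleles exactly without a reference
lookup — the package's round-trip invariant.

## Somatic filter cascade

A call is kept iff VAF ≥ 0.05, it is not on the common-SNP blacklist
(allele-aware by default; position-only mode available), and every
present quality annotation meets its threshold: median base quality ≥ 20,
median mapping quality ≥ 30, SEQQ ≥ 20, GERMQ ≥ 20. SEQQ and GERMQ are
Phred-scaled confidences that a call is *not* a sequencing error or a
germline variant, so high values are evidence in the call's favor and the
cascade keeps values at or above the cut — FilterMutectCalls semantics.
All thresholds are inclusive except the strict `< 0.05` VAF exclusion.
Missing quality fields pass by default (degraded FFPE data rarely carries
every annotation); strict mode fails them, and a missing VAF in strict
mode is an input error. Rejections carry the first failing reason in the
fixed order vaf → snp → base quality → mapping quality → SEQQ → GERMQ.
The cascade is idempotent and monotone in every threshold.

## Fingerprinting

Genotypes are called from allele depths: depth < 10 is a no-call;
otherwise the alt fraction is cut at 0.15/0.85 into hom-ref / het /
hom-alt. Pair concordance is averaged over SNPs called in both samples;
a pair is `matched` at concordance ≥ 0.8 with ≥ 5 comparable SNPs, and
`inconclusive` (never matched) below the comparability floor.

Loss-of-heterozygosity tolerance — scoring het↔hom disagreements as
half-discordant — is available (`loh_half=True`) but off by default: with
a 10-SNP panel it raises the expected concordance of unrelated pairs from
≈0.39 to ≈0.63 (Monte-Carlo at the generator's MAF range), close enough
to the 0.8 threshold that ~8% of true swaps would pass as matched. Raw
concordance keeps that failure rate below ~1%. This is an inherent limit
of a 10-SNP panel: two unrelated donors agree on ≥ 8/10 genotypes about
once in a hundred pairings, so swap detection is probabilistic, not
certain.

## Enrichment statistics

- Count p-value: exact binomial upper tail, exposure = gene targeted
  length / total targeted length. No multiple-testing correction by
  default (the recurrence threshold is a raw P cut); Bonferroni by flag.
- Weighted-score null (optional): Monte-Carlo placement of the cohort's N
  mutations uniformly over targeted positions, scoring the gene per
  permutation from its per-position weights; add-one-corrected tail,
  deterministic given the seed. For a gene with flat weights it converges
  to the binomial tail (cross-checked in the tests).
- Subregion uniformity: per-label two-sided binomial test, doubling the
  smaller tail (the analysis asks about both excess and deficit).
- Densities are mutations / (size in Mb) / number of samples, with a
  whole-target aggregate row.

## Seed retargeting

Canonical site classes only: 7mer-m8 (exact reverse complement of miRNA
nt 2–8), 7mer-A1 (reverse complement of nt 2–7 followed by an A), 8mer
(both). Overlapping matches are reported once at the strongest type. No
context scoring, conservation, or non-canonical sites: the analysis this
supports is set overlap between wild-type and mutant target sets, for
which canonical matching is the appropriate approximation; absolute
target counts from richer predictors will differ. All sequences are
mapped to DNA (U→T, uppercase) at ingest; a seed containing N is
rejected.

## Synthetic data generator

The generator emulates the study design the pipeline targets, not
sequence biology: hairpin bases are uniform random (coordinates, never
folding, drive every implemented analysis).

Defaults, chosen once as the desk-scale version of a realistic cohort:
200 genes / 50 tumor-normal pairs; precursor 55–95 nt; mature arms 19–23
nt, placed flush with the precursor ends with a ≥ 10 nt loop; ~50% minus
strand; 10% of genes single-arm (exercising passenger inference); flanks
25 nt. Mutations are planted per sample, gene, and subregion as Poisson
with mean rate × size × 1, at a default 15 mut/Mb/sample uniformly across
subregions. Mutation types mix 93.9% substitutions, 3.2% deletions, 1.5%
insertions, 1.5% dinucleotide substitutions. VAF ~ Beta(2, 6) (an impure
FFPE-like tumor fraction), resampled to ≥ 0.05 for records meant to
survive filtering. Decoy records violating each filter are added at 10%
(low VAF) / 5% (blacklisted SNP) / 5% (one degraded quality field) of the
passing count and marked `should_pass_filters=false` in the ledger.
Mutect2-style fields go to FORMAT (AF, AD) and INFO (SEQQ, GERMQ, MBQ,
MMQ) to exercise both read paths. The fingerprint panel holds 10 SNPs
with MAF drawn from 0.35–0.5 (fingerprint panels maximize
heterozygosity; comfortably above the MAF > 0.1 design criterion);
genotypes are Hardy-Weinberg draws per donor, with swapped pairs drawing
the tumor from an independent donor. The UTR database plants exact 8mer
sites for a wild-type seed (taken from the first gene's 5p arm) and a
mutant seed (one seed base changed), after scrubbing accidental matches
to either seed from the background sequence; planted counts default to
12 wild-type-only / 8 shared / 10 mutant-only.

Everything derives from one `rng_seed`; a seed reproduces byte-identical
output files. Every VCF record traces to exactly one truth-ledger row.

What passing tests on this generator do **not** show: performance on real
alignments (no read-level simulation, no sequencing-error model, no
FFPE artifact spectrum), hairpin-structure effects, isomiR or germline
complications, or TargetScan-corpus target counts.

## Numerical and reporting choices

- Binomial tails via the survival function of `scipy.stats.binom`
  (stable to n ≈ 10⁴ and far beyond).
- Two-sided uniformity p-values are capped at 1.
- Percentages in reports are always recomputed from counts: whole
  percent for sample fractions, one decimal for mutation-type fractions;
  empty denominators render as undefined rather than 0. Each summary runs
  a self-consistency audit on emission.
- The consensus positional profile pools mature positions beyond 22 at
  bin 22 and keeps only the first/last five loop positions plus a pooled
  middle bin; lower-stem positions (possible on genes whose arms are not
  flush with the precursor) get two explicit pooled stem bins so bin
  counts always sum to the mutation total.
- Test and acceptance problem sizes (200 genes, 50 pairs; 100-replicate
  calibrations; 10⁴ Monte-Carlo permutations) are the package's default
  desk-scale study conditions; the full suite runs in a few seconds.

## Known limitations

- Cleavage-site windows and the motif catalog are stand-ins for
  enzyme-specific definitions; users with curated catalogs should supply
  them as overlays.
- The enrichment exposure model is uniform per base pair within the
  panel; it does not model trinucleotide mutational signatures or
  regional mutability covariates.
- Fingerprint swap detection with 10 SNPs has an irreducible ~1%
  per-pair false-match floor (see above).
- Only tumor-side VCFs are consumed; the package assumes the caller
  already used the matched normal.
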