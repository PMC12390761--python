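"""Cohort-level summaries, consensus positional profile, and panel coverage.

The cohort summary mirrors the layout of a targeted-panel mutation table:
per cancer cohort and overall, the pair count, mutation counts per gene
category (miRNA / biogenesis / driver), the fraction of samples carrying
at least one mutation, and the substitution fraction.  Percentages are
always recomputed from the printed counts — sample fractions rounded to
whole percent, mutation-type fractions to one decimal — and every report
emission runs a self-consistency audit re-deriving each percentage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "CohortSummary",
    "PositionalProfile",
    "cohort_summary",
    "positional_profile",
    "panel_coverage_report",
    "pct_int",
    "pct_1dp",
]

CATEGORIES = ("miRNA", "biogenesis", "driver")


def pct_int(n: int, d: int) -> Optional[int]:
    """Whole-percent rendering used for sample fractions (81 for 227/279)."""
    return None if d == 0 else round(100 * n / d)


def pct_1dp(n: int, d: int) -> Optional[float]:
    """One-decimal rendering used for mutation-type fractions (93.9)."""
    return None if d == 0 else round(1000 * n / d) / 10


@dataclass
class CohortRow:
    cohort: str
    n_pairs: int
    n_mutations: dict                 # category -> count
    n_mutated_samples: dict           # category ("all" + categories) -> count
    n_substitutions: dict             # category ("all" + categories) -> count

    @property
    def total_mutations(self) -> int:
        return sum(self.n_mutations.values())

    def pct_mutated_samples(self, category: str = "all") -> Optional[int]:
        return pct_int(self.n_mutated_samples.get(category, 0), self.n_pairs)

    def pct_substitutions(self, category: str = "all") -> Optional[float]:
        total = self.total_mutations if category == "all" else self.n_mutations.get(category, 0)
        return pct_1dp(self.n_substitutions.get(category, 0), total)

    def category_share_pct(self, category: str) -> Optional[int]:
        return pct_int(self.n_mutations.get(category, 0), self.total_mutations)


@dataclass
class CohortSummary:
    rows: list            # CohortRow per cohort, "all" row first

    def __post_init__(self):
        self.audit()

    @property
    def overall(self) -> CohortRow:
        return self.rows[0]

    def audit(self) -> None:
        """Self-consistency: category counts sum to the total; every
        percentage re-derives from the counts stored beside it."""
        for row in self.rows:
            if sum(row.n_mutations.values()) != row.total_mutations:
                raise AssertionError(f"{row.cohort}: category counts do not sum")
            for cat in ("all", *CATEGORIES):
                p = row.pct_mutated_samples(cat)
                if p is not None and not 0 <= p <= 100:
                    raise AssertionError(f"{row.cohort}: bad sample percentage {p}")

    def to_rows(self) -> list:
        out = []
        for row in self.rows:
            out.append(
                {
                    "cohort": row.cohort,
                    "n_pairs": row.n_pairs,
                    "total_mutations": row.total_mutations,
                    **{f"n_{c}": row.n_mutations.get(c, 0) for c in CATEGORIES},
                    "pct_mutated_samples": row.pct_mutated_samples(),
                    "pct_substitutions": row.pct_substitutions(),
                }
            )
        return out


def cohort_summary(
    records: Sequence[tuple],
    pairs_by_cohort: Mapping[str, int],
) -> CohortSummary:
    """Summarize mutation records into a per-cohort table.

    ``records`` are (sample_id, cohort, category, mutation_type) tuples with
    category in {miRNA, biogenesis, driver}; ``pairs_by_cohort`` gives the
    number of sequenced pairs per cohort (cohorts with zero mutations are
    still reported).
    """
    cohorts = sorted(pairs_by_cohort)
    rows = []
    for name in ["all", *cohorts]:
        sel = records if name == "all" else [r for r in records if r[1] == name]
        n_pairs = sum(pairs_by_cohort.values()) if name == "all" else pairs_by_cohort[name]
        n_mut = Counter(r[2] for r in sel)
        mutated: dict[str, set] = {"all": set()}
        subs = Counter()
        subs_all = 0
        for sample, _cohort, category, mtype in sel:
            mutated["all"].add(sample)
            mutated.setdefault(category, set()).add(sample)
            if mtype == "substitution":
                subs[category] += 1
                subs_all += 1
        rows.append(
            CohortRow(
                cohort=name,
                n_pairs=n_pairs,
                n_mutations={c: n_mut.get(c, 0) for c in CATEGORIES},
                n_mutated_samples={k: len(v) for k, v in mutated.items()},
                n_substitutions={"all": subs_all, **dict(subs)},
            )
        )
    return CohortSummary(rows)


# ---------------------------------------------------------------------------
# consensus positional profile


@dataclass
class PositionalProfile:
    """Mutation counts along a consensus precursor axis.

    Bins, in order: 5' flank -25..-1; 5' lower stem (pooled); mature/duplex
    5p positions 1..22 (beyond-22 pooled at 22); loop first five and last
    five positions plus one pooled middle bin; 3p positions 1..22 (pooled
    at 22); 3' lower stem (pooled); 3' flank +1..+25.
    """

    bins: list            # (label, count) in axis order

    @property
    def total(self) -> int:
        return sum(c for _, c in self.bins)

    def as_dict(self) -> dict:
        return dict(self.bins)


def _profile_bin_labels(flank_len: int = 25) -> list:
    labels = [f"flank5:{-k}" for k in range(flank_len, 0, -1)]
    labels.append("stem5")
    labels += [f"5p:{i}" for i in range(1, 23)]
    labels += [f"loop:first{i}" for i in range(1, 6)]
    labels.append("loop:mid")
    labels += [f"loop:last{i}" for i in range(5, 0, -1)]
    labels += [f"3p:{i}" for i in range(1, 23)]
    labels.append("stem3")
    labels += [f"flank3:+{k}" for k in range(1, flank_len + 1)]
    return labels


def positional_profile(placements: Sequence[tuple], flank_len: int = 25) -> PositionalProfile:
    """Bin mutations onto the consensus precursor axis.

    Each placement is (region, index) where region identifies the part of
    the gene the mutation fell in and index locates it within that part:

    * ``("flank5", -k)`` / ``("flank3", +k)`` — flank offset (pooled at the
      outermost bin when beyond ``flank_len``);
    * ``("5p", i)`` / ``("3p", i)`` — 1-based position within the mature/
      duplex arm (i > 22 pooled at 22);
    * ``("loop", (i, j))`` — position i from the loop start and j from the
      loop end, both 1-based (first/last five kept, middle pooled);
    * ``("stem5", 0)`` / ``("stem3", 0)`` — precursor positions outside
      arms and loop (pooled).
    """
    counts = Counter()
    for region, index in placements:
        if region in ("flank5", "flank3"):
            k = min(abs(int(index)), flank_len)
            counts[f"flank5:{-k}" if region == "flank5" else f"flank3:+{k}"] += 1
        elif region in ("5p", "3p"):
            counts[f"{region}:{min(int(index), 22)}"] += 1
        elif region == "loop":
            i, j = index
            if i <= 5:
                counts[f"loop:first{i}"] += 1
            elif j <= 5:
                counts[f"loop:last{j}"] += 1
            else:
                counts["loop:mid"] += 1
        elif region in ("stem5", "stem3"):
            counts[region] += 1
        else:
            raise ValueError(f"unknown profile region {region!r}")
    return PositionalProfile([(lbl, counts.get(lbl, 0)) for lbl in _profile_bin_labels(flank_len)])


def place_on_consensus(gene, signed_pos: int) -> tuple:
    """Map a signed precursor position of a gene to a consensus placement."""
    L = gene.precursor_len
    if signed_pos < 0:
        return ("flank5", signed_pos)
    if signed_pos > L:
        return ("flank3", signed_pos - L)
    spans = {}
    for arm in ("5p", "3p"):
        if getattr(gene, f"mature_{arm}") is not None:
            spans[arm] = gene.arm_span_rel(arm)
    if not spans:
        raise ValueError("gene without annotated arms cannot be profiled")
    for arm, (s, e) in spans.items():
        if s <= signed_pos <= e:
            return (arm, signed_pos - s + 1)
    if signed_pos < min(s for s, _ in spans.values()):
        return ("stem5", 0)
    if signed_pos > max(e for _, e in spans.values()):
        return ("stem3", 0)
    # between the two arms: apical loop, indexed from both ends
    loop_start, loop_end = spans["5p"][1] + 1, spans["3p"][0] - 1
    return ("loop", (signed_pos - loop_start + 1, loop_end - signed_pos + 1))


def panel_coverage_report(panel_gene_ids, catalog_gene_ids) -> tuple[int, int]:
    """(covered count, rounded percent) of catalog genes present on the panel."""
    panel, catalog = set(panel_gene_ids), set(catalog_gene_ids)
    if not catalog:
        raise ValueError("catalog is empty")
    covered = len(panel & catalog)
    return covered, round(100 * covered / len(catalog))
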