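"""Per-gene over-mutation statistics and subregion density analysis.

The recurrence analysis asks, for each miRNA gene, whether it carries more
mutations than expected if the cohort's N mutations fell uniformly over
the targeted miRNA sequence.  The per-gene exposure is its targeted length
(precursor plus flanks) over the total targeted length, and the count
p-value is the exact binomial upper tail P(X >= k) with X ~
Binomial(N_total, L_gene/L_total).

A gene is flagged recurrently/functionally over-mutated when it reaches
the study thresholds — at least 5 mutations or a functionally weighted
miRMut score of at least 5.5 — and its binomial P falls below 3e-4.  All
three thresholds are configuration constants.

The weighted-score null has no closed form (weights vary within a gene),
so an optional Monte-Carlo tail probability is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .annotate import AnnotatedVariant

__all__ = [
    "FlagConfig",
    "GeneEnrichmentResult",
    "SubregionDensity",
    "mirmut_gene_score",
    "binomial_tail",
    "gene_overmutation_test",
    "score_null_mc",
    "subregion_density",
    "subregion_uniformity_test",
]


@dataclass(frozen=True)
class FlagConfig:
    min_mutations: int = 5
    min_score: float = 5.5
    max_p: float = 3e-4
    bonferroni: bool = False


@dataclass
class GeneEnrichmentResult:
    gene_id: str
    n_mutations: int
    mirmut_score: float
    target_len: int
    p_count: float
    p_score: Optional[float] = None
    recurrent_flag: bool = False

    def __post_init__(self):
        n, s = self.n_mutations, self.mirmut_score
        if not (n * 1.0 - 1e-9 <= s <= n * 2.0 + 1e-9):
            raise ValueError(f"{self.gene_id}: score {s} outside [{n}, {2*n}]")
        for p in (self.p_count, self.p_score):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.gene_id}: p-value {p} outside [0,1]")


@dataclass
class SubregionDensity:
    label: str
    size_bp: int
    n_mutations: int
    density_mut_per_mb_per_sample: float


def mirmut_gene_score(annotated_variants: Sequence[AnnotatedVariant]) -> float:
    """Functionally weighted miRMut score of one gene: sum of mutation weights."""
    return float(sum(av.weight for av in annotated_variants))


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0,1]")
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def gene_overmutation_test(
    per_gene_counts: Mapping[str, int],
    per_gene_target_len: Mapping[str, int],
    per_gene_scores: Optional[Mapping[str, float]] = None,
    n_total: Optional[int] = None,
    l_total: Optional[int] = None,
    flag_config: FlagConfig = FlagConfig(),
) -> list[GeneEnrichmentResult]:
    """Binomial over-mutation test for every gene with nonzero target length.

    ``n_total``/``l_total`` default to the sums over the supplied maps (use
    explicit values when testing a gene subset against a wider panel).
    Genes with zero target length are excluded.  Results are sorted by
    ascending p_count, then gene id.
    """
    if per_gene_scores is None:
        per_gene_scores = {g: float(k) for g, k in per_gene_counts.items()}
    N = int(n_total if n_total is not None else sum(per_gene_counts.values()))
    L = int(l_total if l_total is not None else sum(per_gene_target_len.values()))
    if L <= 0:
        raise ValueError("total target length must be positive")
    n_genes = sum(1 for l in per_gene_target_len.values() if l > 0)
    max_p = flag_config.max_p / n_genes if flag_config.bonferroni and n_genes else flag_config.max_p

    results = []
    for gene_id, length in per_gene_target_len.items():
        if length <= 0:
            continue
        k = int(per_gene_counts.get(gene_id, 0))
        score = float(per_gene_scores.get(gene_id, float(k)))
        p = binomial_tail(min(k, N), N, min(length / L, 1.0))
        flagged = (
            (k >= flag_config.min_mutations or score >= flag_config.min_score) and p < max_p
        )
        results.append(
            GeneEnrichmentResult(
                gene_id=gene_id,
                n_mutations=k,
                mirmut_score=score,
                target_len=length,
                p_count=p,
                recurrent_flag=bool(flagged),
            )
        )
    results.sort(key=lambda r: (r.p_count, r.gene_id))
    return results


def score_null_mc(
    gene_weights: Sequence[float],
    observed_score: float,
    n_total: int,
    l_total: int,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> float:
    """Monte-Carlo tail probability of a gene's weighted score.

    Null: the cohort's ``n_total`` mutations fall uniformly over the
    ``l_total`` targeted positions; a permutation's gene score is the sum
    of the per-position weights of the mutations landing in the gene
    (``gene_weights``, one per targeted position).  Returns the add-one
    corrected fraction of permutations reaching the observed score.
    """
    w = np.asarray(gene_weights, dtype=float)
    if w.size == 0 or l_total <= 0:
        raise ValueError("gene must have targeted positions")
    if observed_score <= 0:
        return 1.0
    rng = np.random.default_rng(rng_seed)
    p_gene = w.size / l_total
    ks = rng.binomial(n_total, p_gene, size=n_perm)
    scores = np.zeros(n_perm)
    for i, k in enumerate(ks):
        if k:
            scores[i] = w[rng.integers(0, w.size, size=k)].sum()
    hits = int(np.count_nonzero(scores >= observed_score - 1e-12))
    return (1 + hits) / (n_perm + 1)


def subregion_density(
    annotated_variants: Sequence[AnnotatedVariant],
    subregion_sizes: Mapping[str, int],
    n_samples: int,
) -> list[SubregionDensity]:
    """Mutation density per subregion label, in mut/Mb per sample.

    Includes a ``total`` aggregate row over all labels.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    counts: dict[str, int] = {label: 0 for label in subregion_sizes}
    for av in annotated_variants:
        if av.subregion_label in counts:
            counts[av.subregion_label] += 1
    rows = []
    for label, size in subregion_sizes.items():
        if size <= 0:
            raise ValueError(f"subregion {label!r} has non-positive size")
        dens = counts[label] / (size / 1e6) / n_samples
        rows.append(SubregionDensity(label, size, counts[label], dens))
    total_size = sum(subregion_sizes.values())
    total_n = sum(counts.values())
    rows.append(
        SubregionDensity("total", total_size, total_n, total_n / (total_size / 1e6) / n_samples)
    )
    return rows


def _two_sided_binomial(k: int, n: int, p: float) -> float:
    """Two-sided binomial p-value by doubling the smaller tail (capped at 1)."""
    lower = float(stats.binom.cdf(k, n, p))
    upper = binomial_tail(k, n, p)
    return min(1.0, 2.0 * min(lower, upper))


def subregion_uniformity_test(
    annotated_variants: Sequence[AnnotatedVariant],
    subregion_sizes: Mapping[str, int],
) -> dict[str, float]:
    """Per-label two-sided binomial test of uniform mutation placement.

    For each label, k_label observed mutations are tested against
    Binomial(N, size_label/size_total); small p-values indicate either an
    excess or a deficit relative to the label's share of the target.
    """
    total = sum(subregion_sizes.values())
    if total <= 0:
        raise ValueError("total subregion size must be positive")
    counts: dict[str, int] = {label: 0 for label in subregion_sizes}
    for av in annotated_variants:
        if av.subregion_label in counts:
            counts[av.subregion_label] += 1
    N = sum(counts.values())
    out = {}
    for label, size in subregion_sizes.items():
        frac = size / total
        out[label] = 1.0 if frac >= 1.0 else _two_sided_binomial(counts[label], N, frac)
    return out
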