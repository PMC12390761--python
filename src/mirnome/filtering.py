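"""Post-caller somatic filter cascade.

Consumes Mutect2/FilterMutectCalls-style calls that already passed the
caller and applies the study-level cascade: variant allele fraction,
common-SNP blacklist, median base and mapping quality of the alternative
reads, and the SEQQ (not a sequencing error) and GERMQ (not a germline
variant) Phred-scaled qualities.

A variant is kept iff VAF >= min_vaf, it is not blacklisted, and every
*present* quality field meets its threshold (inclusive).  High SEQQ/GERMQ
indicate confidence that the call is somatic, so values at or above the cut
are kept — this follows FilterMutectCalls semantics.  Missing quality
fields pass by default; ``strict=True`` fails them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .annotate import Variant

__all__ = ["FilterConfig", "FilterInputError", "apply_somatic_filters", "REASONS"]

# fixed evaluation order; a rejection carries the first failing reason
REASONS = ("low_vaf", "common_snp", "low_median_base_q", "low_median_map_q", "low_seqq", "low_germq")


class FilterInputError(ValueError):
    """A variant lacks a required field in strict mode."""


@dataclass
class FilterConfig:
    min_vaf: float = 0.05
    min_seqq: float = 20.0
    min_germq: float = 20.0
    min_median_base_q: float = 20.0
    min_median_map_q: float = 30.0
    snp_blacklist: frozenset = frozenset()   # of (chrom, pos, ref, alt) or (chrom, pos)
    position_only_blacklist: bool = False
    strict: bool = False

    def __post_init__(self):
        for name in ("min_vaf", "min_seqq", "min_germq", "min_median_base_q", "min_median_map_q"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("min_seqq", "min_germq", "min_median_base_q", "min_median_map_q"):
            if getattr(self, name) > 99:
                raise ValueError(f"{name} is Phred-scaled and must be <= 99")
        self.snp_blacklist = frozenset(self.snp_blacklist)


def _blacklisted(v: Variant, cfg: FilterConfig) -> bool:
    if cfg.position_only_blacklist:
        return (v.chrom, v.pos) in cfg.snp_blacklist
    return (v.chrom, v.pos, v.ref, v.alt) in cfg.snp_blacklist


def failing_reason(v: Variant, cfg: FilterConfig) -> Optional[str]:
    """First failing filter for a variant, or None if it passes the cascade."""
    if v.vaf is None:
        if cfg.strict:
            raise FilterInputError(f"{v.chrom}:{v.pos} {v.ref}>{v.alt} lacks VAF in strict mode")
    elif v.vaf < cfg.min_vaf:
        return "low_vaf"
    if _blacklisted(v, cfg):
        return "common_snp"
    checks = (
        ("low_median_base_q", v.median_base_q, cfg.min_median_base_q),
        ("low_median_map_q", v.median_map_q, cfg.min_median_map_q),
        ("low_seqq", v.seqq, cfg.min_seqq),
        ("low_germq", v.germq, cfg.min_germq),
    )
    for reason, value, threshold in checks:
        if value is None:
            if cfg.strict:
                return reason
            continue
        if value < threshold:
            return reason
    return None


def apply_somatic_filters(
    variants: Iterable[Variant], config: FilterConfig = FilterConfig()
) -> tuple[list[Variant], list[tuple[Variant, str]]]:
    """Split variants into (kept, rejected_with_reasons).

    Rejections carry the first failing reason in the fixed order
    vaf -> snp -> base_q -> map_q -> seqq -> germq.  The cascade is
    idempotent and monotone: raising any threshold never grows the kept set.
    """
    kept: list[Variant] = []
    rejected: list[tuple[Variant, str]] = []
    for v in variants:
        reason = failing_reason(v, config)
        if reason is None:
            kept.append(v)
        else:
            rejected.append((v, reason))
    return kept, rejected


def load_snp_blacklist(path: str) -> frozenset:
    """Load a blacklist from a 4-column TSV (chrom, pos, ref, alt) or a VCF."""
    entries = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) >= 5 and cols[1].isdigit():  # VCF body line
                chrom, pos, _id, ref, alt = cols[:5]
            elif len(cols) >= 4:
                chrom, pos, ref, alt = cols[:4]
            else:
                raise ValueError(f"blacklist line with {len(cols)} columns: {line!r}")
            for a in alt.split(","):
                entries.add((chrom, int(pos), ref.upper(), a.upper()))
    return frozenset(entries)
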