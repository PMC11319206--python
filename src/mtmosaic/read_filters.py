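"""Variant-level QC filters on read-support summaries.

The filters operate on per-(clone, variant) summaries computed upstream
from the supporting reads (means over supporting reads for mapping and base
quality and for the relative position of the variant base).  Thresholds are
applied as printed: boundary values (mapq 25, baseq 15, position fraction
0.15/0.85, forward fraction 0.10/0.90) pass; five or more mismatches fail.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import VariantRecord

#: low-complexity / reference-gap regions excluded from calling
BLACKLIST_RANGES: tuple[tuple[int, int], ...] = (
    (302, 315),      # ACCCCCCCTCCCCC homopolymer misalignment
    (513, 525),      # GCACACACACACC repeat
    (3105, 3109),    # N gap in the reference
    (16182, 16187),  # ACCCCC homopolymer
)

#: loci where short-read InDel calls are irreproducible (C homopolymers)
NOISY_INDEL_POSITIONS: frozenset[int] = frozenset({567, 955, 5894})

MIN_MAPQ = 25.0
MIN_BASEQ = 15.0
POSITION_FRACTION_RANGE = (0.15, 0.85)
FORWARD_FRACTION_RANGE = (0.10, 0.90)
MAX_MISMATCHES = 5  # five or more mismatches fail
MAX_ADDITIONAL_INDEL_FRACTION = 0.5


@dataclass(frozen=True)
class ReadSupportSummary:
    """Summary of the reads supporting one variant call in one clone."""

    mean_mapq: float
    mean_baseq: float
    mean_position_fraction: float
    forward_fraction: float
    max_mismatches: int
    pairing_ok: bool = True
    frac_additional_indels: float | None = None  # InDels only

    def __post_init__(self) -> None:
        for name in ("mean_position_fraction", "forward_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} {value} outside [0, 1]")
        if self.mean_mapq < 0 or self.mean_baseq < 0:
            raise ValueError("qualities must be >= 0")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()


def in_blacklist(position: int) -> bool:
    return any(lo <= position <= hi for lo, hi in BLACKLIST_RANGES)


def apply_read_filters(v: VariantRecord, s: ReadSupportSummary) -> FilterVerdict:
    """Apply the five read-level criteria plus blacklist and InDel rules;
    every triggered reason is reported."""
    reasons: list[str] = []
    if s.mean_mapq < MIN_MAPQ:
        reasons.append("low_mapq")
    if s.mean_baseq < MIN_BASEQ:
        reasons.append("low_baseq")
    lo, hi = POSITION_FRACTION_RANGE
    if s.mean_position_fraction < lo or s.mean_position_fraction > hi:
        reasons.append("skewed_read_position")
    lo, hi = FORWARD_FRACTION_RANGE
    if s.forward_fraction < lo or s.forward_fraction > hi:
        reasons.append("strand_imbalance")
    if s.max_mismatches >= MAX_MISMATCHES:
        reasons.append("excess_mismatches")
    if not s.pairing_ok:
        reasons.append("improper_pairing")
    if in_blacklist(v.position):
        reasons.append("blacklist")
    if v.variant_type in ("insertion", "deletion"):
        if s.frac_additional_indels is None:
            raise ValueError(
                f"frac_additional_indels required for {v.variant_type} at "
                f"position {v.position}"
            )
        if s.frac_additional_indels > MAX_ADDITIONAL_INDEL_FRACTION:
            reasons.append("additional_indels")
        if v.position in NOISY_INDEL_POSITIONS:
            reasons.append("noisy_indel_locus")
    return FilterVerdict(passed=not reasons, reasons=tuple(reasons))


def filter_table(variants, summaries) -> list[FilterVerdict]:
    """Vector convenience: apply the filters pairwise over two sequences."""
    if len(variants) != len(summaries):
        raise ValueError("variants and summaries must align")
    return [apply_read_filters(v, s) for v, s in zip(variants, summaries)]
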