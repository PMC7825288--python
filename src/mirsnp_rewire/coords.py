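"""Coordinate conventions.

GFF3 and VCF are 1-based inclusive at every file interface; everything in memory is
0-based half-open. This module is the single audited place where the conversion
happens — no other module may add or subtract 1 from a genomic coordinate.
"""

from __future__ import annotations


def to_internal(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open interval."""
    if start_1based < 1 or end_1based_inclusive < start_1based:
        raise ValueError(
            f"invalid 1-based interval [{start_1based}, {end_1based_inclusive}]"
        )
    return start_1based - 1, end_1based_inclusive


def to_gff(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive interval."""
    if start0 < 0 or end0 <= start0:
        raise ValueError(f"invalid 0-based interval [{start0}, {end0})")
    return start0 + 1, end0


def point_to_internal(pos_1based: int) -> int:
    """1-based position (VCF POS) -> 0-based index."""
    if pos_1based < 1:
        raise ValueError(f"invalid 1-based position {pos_1based}")
    return pos_1based - 1


def point_to_vcf(pos0: int) -> int:
    """0-based index -> 1-based position (VCF POS)."""
    if pos0 < 0:
        raise ValueError(f"invalid 0-based position {pos0}")
    return pos0 + 1
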