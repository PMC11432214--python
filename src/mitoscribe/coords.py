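"""Circular-coordinate arithmetic.

All genomic coordinates in this package are 1-based, fully closed intervals
on the J-strand reference of a circular molecule.  An interval may wrap the
origin (start > end), in which case it covers ``start..L`` followed by
``1..end``.
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

Segment = Tuple[int, int]


class CoordinateError(ValueError):
    """A coordinate lies outside ``[1, genome_length]``."""


def check_position(pos: int, genome_length: int) -> int:
    if not 1 <= pos <= genome_length:
        raise CoordinateError(
            f"position {pos} outside [1, {genome_length}]"
        )
    return pos


def wrap_position(pos: int, genome_length: int) -> int:
    """Map any integer onto the circle (1-based)."""
    return (pos - 1) % genome_length + 1


def span_length(start: int, end: int, genome_length: int, wraps: bool = False) -> int:
    """Number of positions covered by a closed circular interval."""
    check_position(start, genome_length)
    check_position(end, genome_length)
    if wraps or start > end:
        return genome_length - start + 1 + end
    return end - start + 1


def segments(start: int, end: int, genome_length: int, wraps: bool = False) -> List[Segment]:
    """Decompose a (possibly wrapping) interval into linear closed segments."""
    check_position(start, genome_length)
    check_position(end, genome_length)
    if wraps or start > end:
        return [(start, genome_length), (1, end)]
    return [(start, end)]


def positions(start: int, end: int, genome_length: int, wraps: bool = False) -> Iterator[int]:
    """Enumerate every covered position (brute-force helper)."""
    for s, e in segments(start, end, genome_length, wraps):
        yield from range(s, e + 1)


def _seg_overlap(a: Segment, b: Segment) -> int:
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    return max(0, hi - lo + 1)


def overlap_length(
    a: Tuple[int, int, bool],
    b: Tuple[int, int, bool],
    genome_length: int,
) -> int:
    """Overlap in bp between two circular intervals ``(start, end, wraps)``."""
    sa = segments(a[0], a[1], genome_length, a[2])
    sb = segments(b[0], b[1], genome_length, b[2])
    return sum(_seg_overlap(x, y) for x in sa for y in sb)


def circular_gap(end_a: int, start_b: int, genome_length: int) -> int:
    """Signed gap walking forward on the circle from ``end_a`` to ``start_b``.

    0 means flush (start_b immediately follows end_a); positive values are
    spacer widths; negative values are overlaps expressed as ``-overlap_bp``.
    The gap is reported in ``[-L/2, L/2)`` so small overlaps near the origin
    are seen as overlaps rather than near-full-circle spacers.
    """
    g = (start_b - end_a - 1) % genome_length
    if g >= genome_length // 2:
        g -= genome_length
    return g


def circular_distance(a: int, b: int, genome_length: int) -> int:
    """Shortest distance between two positions on the circle."""
    d = abs(a - b) % genome_length
    return min(d, genome_length - d)
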