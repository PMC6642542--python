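"""Genomic coordinate primitives shared by every other module.

Internally everything is 0-based, half-open ``[start, end)`` — the BAM/BED
convention. User-facing region strings follow the genome-browser convention
instead: 1-based, fully closed, with optional thousands-separator commas
(``chr1:1,000-2,000``). The conversion happens exactly once, in
:func:`parse_region`, and is undone by ``str(region)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import RegionParseError

__all__ = ["GenomicRegion", "Interval", "parse_region", "clip_interval"]


@dataclass(frozen=True)
class GenomicRegion:
    """A single-chromosome window, 0-based half-open.

    Attributes
    ----------
    chrom:
        Chromosome name, verbatim as it appears in the input files. No
        ``chr1`` / ``1`` aliasing is ever attempted: a naming mismatch with a
        BAM header is surfaced downstream instead of silently papered over.
    start, end:
        0-based half-open bounds; ``end > start`` so the region is never
        empty.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom or ":" in self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        # back to the 1-based inclusive convention users typed
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open interval with an optional display label."""

    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval end must exceed start, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


def _parse_coordinate(token: str, text: str) -> int:
    digits = token.replace(",", "")
    if not digits.isdigit():
        raise RegionParseError(
            f"cannot parse region {text!r}: {token!r} is not a positive integer coordinate"
        )
    return int(digits)


def parse_region(text: str) -> GenomicRegion:
    """Parse a browser-style region string into a :class:`GenomicRegion`.

    The input is ``CHROM:START-END`` with 1-based inclusive coordinates;
    thousands-separator commas are stripped. The result is 0-based half-open,
    so ``"chr1:100-200"`` becomes ``GenomicRegion("chr1", 99, 200)`` of
    length 101.
    """
    stripped = text.strip()
    head, sep, span = stripped.rpartition(":")
    if not sep or not head:
        raise RegionParseError(
            f"cannot parse region {text!r}: expected CHROM:START-END (missing ':')"
        )
    lo, sep, hi = span.partition("-")
    if not sep or not lo or not hi:
        raise RegionParseError(
            f"cannot parse region {text!r}: expected START-END after the chromosome, got {span!r}"
        )
    start1 = _parse_coordinate(lo, text)
    end1 = _parse_coordinate(hi, text)
    if start1 == 0:
        raise RegionParseError(
            f"cannot parse region {text!r}: coordinates are 1-based, position 0 does not exist"
        )
    if start1 > end1:
        raise RegionParseError(
            f"cannot parse region {text!r}: start {start1} is greater than end {end1}"
        )
    try:
        return GenomicRegion(head, start1 - 1, end1)
    except ValueError as exc:
        raise RegionParseError(f"cannot parse region {text!r}: {exc}") from exc


def clip_interval(iv: Interval, region: GenomicRegion) -> Optional[Interval]:
    """Intersect ``iv`` with the region window; ``None`` when disjoint.

    Half-open semantics: an interval abutting the region boundary does not
    overlap it. The label is preserved.
    """
    start = max(iv.start, region.start)
    end = min(iv.end, region.end)
    if end <= start:
        return None
    return Interval(start, end, iv.label)
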