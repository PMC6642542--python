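"""Per-base coverage over a region for every replicate, with optional
counts-per-million scaling, binning, and per-group averaging.

Depth follows standard pileup semantics: a read contributes to a reference
base only where a reference-consuming *aligned* CIGAR operation (M, ``=``,
X) spans it. Deletions (D) and spliced skips (N) consume reference but add
no depth, so spliced RNA-seq reads do not paint their introns — which
matters when mixing data types in one figure. Secondary, supplementary and
unmapped records are always excluded; mapping-quality and duplicate
filtering are opt-in.

Normalization is deliberately off by default: raw counts are what the tool
promises to show, and CPM scaling exists to *inspect* normalization, not to
apply it silently. When enabled it is applied per sample, before group
averaging.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .config import SampleGroup, bam_index_path
from .errors import CoverageError
from .regions import GenomicRegion

__all__ = [
    "ReadFilter",
    "CoverageTrack",
    "GroupProfile",
    "compute_coverage",
    "library_size",
    "normalize_track",
    "bin_track",
    "group_profiles",
    "make_group_profile",
    "write_bedgraph",
]

# CIGAR operation codes (SAM spec): which consume reference, which add depth
_REF_CONSUMING = frozenset({0, 2, 3, 7, 8})  # M D N = X
_DEPTH_OPS = frozenset({0, 7, 8})  # M = X


@dataclass(frozen=True)
class ReadFilter:
    """Which alignment records count toward depth.

    Secondary, supplementary and unmapped records are unconditionally
    excluded. ``min_mapq`` keeps only records with mapping quality at or
    above the threshold; ``exclude_duplicates`` drops PCR/optical duplicate
    flags (kept by default — dedup policy belongs upstream).
    """

    min_mapq: int = 0
    exclude_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError(f"min_mapq must be >= 0, got {self.min_mapq}")

    def keeps(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        return True


@dataclass(frozen=True)
class CoverageTrack:
    """Depth vector for one sample over the region.

    ``values`` has one entry per base (``bin_size == 1``) or per bin, in
    region order; length is ``ceil(region.length / bin_size)``. Raw unbinned
    tracks hold non-negative integers; normalized tracks hold CPM floats.
    """

    region: GenomicRegion
    values: np.ndarray
    sample_label: str
    normalized: bool = False
    bin_size: int = 1

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        expected = math.ceil(self.region.length / self.bin_size)
        if values.ndim != 1 or values.size != expected:
            raise ValueError(
                f"track {self.sample_label!r}: expected {expected} values for "
                f"region length {self.region.length} at bin size {self.bin_size}, "
                f"got shape {values.shape}"
            )
        if values.size and values.min() < 0:
            raise ValueError(f"track {self.sample_label!r}: negative coverage value")


@dataclass(frozen=True)
class GroupProfile:
    """All replicate tracks of one group plus their elementwise mean."""

    group_name: str
    replicate_tracks: tuple[CoverageTrack, ...]
    mean_track: CoverageTrack


def _open_indexed(bam: Union[str, Path]) -> pysam.AlignmentFile:
    bam = Path(bam)
    if not bam.exists():
        raise CoverageError(f"BAM file not found: {bam}")
    if bam_index_path(bam) is None:
        raise CoverageError(
            f"BAM index not found for {bam}; create one with: samtools index {bam}"
        )
    return pysam.AlignmentFile(str(bam))


def compute_coverage(
    bam: Union[str, Path],
    region: GenomicRegion,
    read_filter: Optional[ReadFilter] = None,
    sample_label: Optional[str] = None,
) -> CoverageTrack:
    """Per-base pileup depth of one BAM over the region.

    ``values[i]`` is the number of filtered reads whose aligned blocks
    (CIGAR M/=/X) cover base ``region.start + i``. Reads partially
    overlapping the window contribute only inside it. A chromosome absent
    from the BAM header yields an all-zero track plus a ``UserWarning``
    rather than an error, so partial contig sets can still be overlaid.
    """
    read_filter = read_filter or ReadFilter()
    bam = Path(bam)
    label = sample_label if sample_label is not None else bam.stem
    values = np.zeros(region.length, dtype=np.int64)
    with _open_indexed(bam) as af:
        if region.chrom not in af.references:
            warnings.warn(
                f"chromosome {region.chrom!r} not present in {bam.name}; "
                "returning all-zero coverage",
                UserWarning,
                stacklevel=2,
            )
            return CoverageTrack(region, values, label)
        for read in af.fetch(region.chrom, region.start, region.end):
            if not read_filter.keeps(read):
                continue
            cigar = read.cigartuples
            if cigar is None:
                continue
            pos = read.reference_start
            for op, length in cigar:
                if op in _DEPTH_OPS:
                    lo = max(pos, region.start)
                    hi = min(pos + length, region.end)
                    if hi > lo:
                        values[lo - region.start : hi - region.start] += 1
                if op in _REF_CONSUMING:
                    pos += length
    return CoverageTrack(region, values, label)


def library_size(bam: Union[str, Path]) -> int:
    """Number of mapped, primary, non-supplementary records in the whole file.

    This is the denominator for CPM scaling. The file is scanned record by
    record so that secondary and supplementary alignments are excluded
    exactly, which raw index statistics cannot guarantee.
    """
    with _open_indexed(bam) as af:
        return sum(
            1
            for read in af.fetch(until_eof=True)
            if not (read.is_unmapped or read.is_secondary or read.is_supplementary)
        )


def normalize_track(track: CoverageTrack, lib_size: int) -> CoverageTrack:
    """Scale a raw track to counts-per-million: ``values * 1e6 / lib_size``."""
    if track.normalized:
        raise CoverageError(f"track {track.sample_label!r} is already normalized")
    if lib_size <= 0:
        raise CoverageError(
            f"cannot normalize {track.sample_label!r}: library size is {lib_size} "
            "(empty library)"
        )
    return replace(
        track, values=track.values.astype(float) * (1e6 / lib_size), normalized=True
    )


def bin_track(track: CoverageTrack, bin_size: int) -> CoverageTrack:
    """Average base-level values into fixed-width bins.

    The final bin may be narrower; it is averaged over its actual width so
    width-weighted sums are conserved. ``bin_size == 1`` is the identity.
    """
    if bin_size < 1:
        raise CoverageError(f"bin_size must be >= 1, got {bin_size}")
    if track.bin_size != 1:
        raise CoverageError("track is already binned; bin from a base-level track")
    if bin_size == 1:
        return track
    n = track.values.size
    starts = np.arange(0, n, bin_size)
    sums = np.add.reduceat(track.values.astype(float), starts)
    widths = np.minimum(starts + bin_size, n) - starts
    return replace(track, values=sums / widths, bin_size=bin_size)


def make_group_profile(
    group_name: str, tracks: Sequence[CoverageTrack]
) -> GroupProfile:
    """Assemble a :class:`GroupProfile`, computing the elementwise mean track.

    All tracks must share region, bin size and normalization state; each
    group is averaged over its own number of replicates, so unequal group
    sizes are fine.
    """
    if not tracks:
        raise CoverageError(f"group {group_name!r} has no coverage tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.region != first.region
            or t.bin_size != first.bin_size
            or t.normalized != first.normalized
        ):
            raise CoverageError(
                f"group {group_name!r}: tracks disagree on region/bin/normalization"
            )
    mean = np.mean([t.values for t in tracks], axis=0)
    mean_track = CoverageTrack(
        first.region, mean, f"{group_name} (mean)", first.normalized, first.bin_size
    )
    return GroupProfile(group_name, tuple(tracks), mean_track)


def group_profiles(
    groups: Sequence[SampleGroup],
    region: GenomicRegion,
    read_filter: Optional[ReadFilter] = None,
    normalize: bool = False,
    bin_size: int = 1,
) -> list[GroupProfile]:
    """Compute every group's replicate tracks and mean track.

    All samples use identical filter, normalization and binning settings.
    Errors from individual samples are re-raised tagged with the sample
    label so the failing input is obvious.
    """
    profiles = []
    for group in groups:
        tracks = []
        for rec in group.samples:
            try:
                track = compute_coverage(rec.bam_path, region, read_filter, rec.label)
                if normalize:
                    track = normalize_track(track, library_size(rec.bam_path))
                if bin_size != 1:
                    track = bin_track(track, bin_size)
            except CoverageError as exc:
                raise CoverageError(f"sample {rec.label!r}: {exc}") from exc
            tracks.append(track)
        profiles.append(make_group_profile(group.name, tracks))
    return profiles


def write_bedgraph(track: CoverageTrack, path: Union[str, Path]) -> Path:
    """Export a track as 4-column BEDGRAPH (0-based half-open).

    Runs of equal adjacent values are merged; zero runs are written too so
    the file tiles the region exactly — handy for cross-checking the drawn
    values in an external browser.
    """
    path = Path(path)
    region = track.region
    values = track.values
    lines = []
    run_start = 0
    for i in range(1, values.size + 1):
        if i == values.size or values[i] != values[run_start]:
            lo = region.start + run_start * track.bin_size
            hi = min(region.start + i * track.bin_size, region.end)
            lines.append(f"{region.chrom}\t{lo}\t{hi}\t{values[run_start]:g}")
            run_start = i
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
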