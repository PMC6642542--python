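"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's code paths: the pileup oracle parses
CIGAR strings from the declarative read specs with a regex and walks bases
one by one in pure Python; the overlap and depth oracles are exhaustive
scans. Slow, obvious, and correct by inspection.
"""

from __future__ import annotations

import re

import numpy as np

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def bruteforce_pileup(reads, region, min_mapq=0, exclude_duplicates=False):
    """Per-base depth by expanding every read's aligned blocks base by base."""
    cov = np.zeros(region.end - region.start, dtype=np.int64)
    for r in reads:
        if r.unmapped or r.secondary or r.supplementary:
            continue
        if r.mapq < min_mapq:
            continue
        if exclude_duplicates and r.duplicate:
            continue
        if r.chrom != region.chrom:
            continue
        pos = r.pos - 1  # 1-based spec -> 0-based
        for num, op in _CIG.findall(r.cigar):
            num = int(num)
            if op in "M=X":
                for p in range(pos, pos + num):
                    if region.start <= p < region.end:
                        cov[p - region.start] += 1
            if op in "MDN=X":
                pos += num
    return cov


def bruteforce_aligned_bases_in_region(reads, region, min_mapq=0,
                                       exclude_duplicates=False):
    """Total M/=/X bases of kept reads falling inside the region."""
    return int(
        bruteforce_pileup(reads, region, min_mapq, exclude_duplicates).sum()
    )


def bruteforce_overlap_scan(rows, region):
    """All (start, end, name) BED rows overlapping the region, clipped.

    ``rows`` are (chrom, start, end, name) tuples in 0-based half-open
    coordinates; output sorted by (start, end).
    """
    hits = []
    for chrom, start, end, name in rows:
        if chrom != region.chrom:
            continue
        lo, hi = max(start, region.start), min(end, region.end)
        if hi > lo:
            hits.append((lo, hi, name))
    return sorted(hits, key=lambda t: (t[0], t[1]))


def sweepline_max_depth(intervals):
    """Maximum pointwise overlap depth of half-open intervals."""
    events = []
    for iv in intervals:
        events.append((iv.start, 1))
        events.append((iv.end, -1))
    depth = best = 0
    for _, delta in sorted(events):  # ends (-1) sort before starts (+1) at ties
        depth += delta
        best = max(best, depth)
    return best


def interval_union(pairs):
    """Union of (start, end) half-open pairs via sorted sweep."""
    merged = []
    for start, end in sorted(pairs):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(m) for m in merged]
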