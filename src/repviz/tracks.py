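"""Feature (BED) and gene-model (GTF) tracks for the display region.

BED is consumed 0-based half-open, GTF 1-based inclusive; both are converted
to the internal half-open convention at the parser boundary and nowhere
else. Only BED columns 1-4 are interpreted — peak-caller output varies
wildly beyond the name column, and only peak extents are drawn. Gene models
are flattened per gene: exons from all transcripts are merged into one
union, giving a single compact row per gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import gffutils

from .config import FeatureTrackConfig
from .errors import TrackError
from .regions import GenomicRegion, Interval, clip_interval

__all__ = [
    "FeatureInterval",
    "FeatureTrack",
    "GeneModel",
    "load_features",
    "load_gene_models",
    "assign_stack_rows",
    "merge_intervals",
]


@dataclass(frozen=True)
class FeatureInterval:
    """One BED feature clipped to the display region."""

    interval: Interval
    name: Optional[str] = None


@dataclass(frozen=True)
class FeatureTrack:
    """All features of one BED file inside the region; may be empty."""

    label: str
    features: tuple[FeatureInterval, ...]


@dataclass(frozen=True)
class GeneModel:
    """One gene flattened to its exon union.

    ``span`` covers the full gene (which may extend past the display
    region); exons are pairwise disjoint and sorted.
    """

    gene_name: str
    strand: str
    span: Interval
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_name!r} has no exons")


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def load_features(cfg: FeatureTrackConfig, region: GenomicRegion) -> FeatureTrack:
    """Load one BED file, keeping only features overlapping the region.

    Features are clipped to the window and sorted by start; the BED name
    column (4) becomes the feature name when present. ``track``/``browser``/
    comment lines are skipped silently; malformed data lines raise with
    their line number.
    """
    path = Path(cfg.bed_path)
    if not path.exists():
        raise TrackError(f"BED file not found: {path}")
    features: list[FeatureInterval] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrackError(
                    f"{path}:{lineno}: expected >= 3 tab-separated BED columns, "
                    f"got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise TrackError(
                    f"{path}:{lineno}: non-integer BED coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            if end <= start:
                raise TrackError(
                    f"{path}:{lineno}: BED end ({end}) must exceed start ({start})"
                )
            if chrom != region.chrom:
                continue
            name = fields[3].strip() if len(fields) >= 4 and fields[3].strip() else None
            clipped = clip_interval(Interval(start, end), region)
            if clipped is not None:
                features.append(FeatureInterval(clipped, name))
    features.sort(key=lambda f: (f.interval.start, f.interval.end))
    return FeatureTrack(cfg.label, tuple(features))


def merge_intervals(intervals: Sequence[Interval]) -> tuple[Interval, ...]:
    """Union of intervals: sorted, overlapping/abutting runs merged."""
    if not intervals:
        return ()
    ordered = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = Interval(last.start, iv.end)
        else:
            merged.append(Interval(iv.start, iv.end))
    return tuple(Interval(iv.start, iv.end) for iv in merged)


def _prescan_gtf(path: Path) -> None:
    """Cheap structural validation so errors carry line numbers."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise TrackError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise TrackError(
                    f"{path}:{lineno}: non-integer GTF coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if end < start:
                raise TrackError(
                    f"{path}:{lineno}: GTF end ({end}) before start ({start})"
                )
            if fields[2] == "exon" and "gene_id" not in fields[8] and "gene_name" not in fields[8]:
                raise TrackError(
                    f"{path}:{lineno}: exon line carries neither gene_id nor "
                    f"gene_name in its attribute column"
                )


def load_gene_models(
    gtf: Union[str, Path], region: GenomicRegion
) -> list[GeneModel]:
    """Load genes whose span overlaps the region from an Ensembl-style GTF.

    One model per gene: exon features are grouped by ``gene_id``, merged to
    their union, and labelled with ``gene_name`` (falling back to
    ``gene_id``). GTF's 1-based inclusive coordinates become 0-based
    half-open. Spans are *not* clipped here; the renderer clips at draw time.
    """
    path = Path(gtf)
    if not path.exists():
        raise TrackError(f"GTF file not found: {path}")
    _prescan_gtf(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises bare/varied exception types
        raise TrackError(f"failed to parse GTF {path}: {exc}") from exc

    per_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        if exon.seqid != region.chrom:
            continue
        gene_id = exon.attributes.get("gene_id", [None])[0]
        gene_name = exon.attributes.get("gene_name", [None])[0]
        key = gene_id or gene_name
        if key is None:
            raise TrackError(
                f"{path}: exon at {exon.seqid}:{exon.start}-{exon.end} has no "
                "gene_id or gene_name attribute"
            )
        entry = per_gene.setdefault(
            key, {"name": gene_name or gene_id, "strand": exon.strand or ".", "exons": []}
        )
        entry["exons"].append(Interval(exon.start - 1, exon.end))

    models = []
    for entry in per_gene.values():
        exons = merge_intervals(entry["exons"])
        span = Interval(exons[0].start, exons[-1].end)
        if span.start < region.end and span.end > region.start:
            strand = entry["strand"] if entry["strand"] in {"+", "-"} else "."
            models.append(GeneModel(entry["name"], strand, span, exons))
    models.sort(key=lambda g: (g.span.start, g.span.end, g.gene_name))
    return models


def assign_stack_rows(items: Sequence[Interval]) -> list[int]:
    """Greedy first-fit row assignment so overlapping glyphs never collide.

    Items are considered in start order; each takes the lowest row whose
    previous occupant ends at or before its start (half-open, so abutting
    items may share a row). For inputs processed in start order this uses
    exactly the maximum pointwise overlap depth — the optimum. The returned
    list is aligned with the *input* order.
    """
    rows = [0] * len(items)
    row_ends: list[int] = []
    for idx in sorted(range(len(items)), key=lambda i: (items[i].start, items[i].end)):
        iv = items[idx]
        for r, end in enumerate(row_ends):
            if end <= iv.start:
                row_ends[r] = iv.end
                rows[idx] = r
                break
        else:
            row_ends.append(iv.end)
            rows[idx] = len(row_ends) - 1
    return rows
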