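"""Multi-panel figure assembly.

Panel order is fixed: one coverage panel per group (config order), then one
panel overlaying every group's mean, then a stacked feature panel when BED
tracks are configured, then the gene-model panel when an annotation was
given. Every coverage panel — replicates and means alike — shares a single
vertical scale equal to the global replicate maximum, so intra- and
intergroup variation are visually comparable; means never exceed replicate
maxima, so the shared ceiling is always sufficient.

Coverage is drawn as translucent filled step profiles so overlapping
replicates stay visible. Replicate colors come from a fixed 8-color
colorblind-safe palette, assigned by global replicate slot (cycling past 8);
a group's mean reuses the color of that group's first replicate slot, which
keeps the average panel's lines distinguishable between groups.

Rendering is deterministic: identical specs yield byte-identical SVG (text
kept as text, no timestamps, fixed hash salt).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib as mpl
import numpy as np
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle
from matplotlib.ticker import MaxNLocator

from .coverage import CoverageTrack, GroupProfile
from .errors import RenderError
from .regions import GenomicRegion, Interval, clip_interval
from .tracks import FeatureTrack, GeneModel, assign_stack_rows

__all__ = ["PALETTE", "FigureSpec", "build_figure_spec", "compose_figure", "render"]

SUPPORTED_FORMATS = ("png", "pdf", "svg")

# Wong (2011) colorblind-safe palette, reordered for contrast between
# neighbouring replicate slots; cycles when a figure has > 8 replicates.
PALETTE = (
    "#0072B2",  # blue
    "#D55E00",  # vermillion
    "#009E73",  # bluish green
    "#CC79A7",  # reddish purple
    "#E69F00",  # orange
    "#56B4E9",  # sky blue
    "#F0E442",  # yellow
    "#999999",  # grey
)

AVERAGE_PANEL_LABEL = "coverage:__average__"
_GLYPH_COLOR = "#3b3b3b"


@dataclass(frozen=True)
class FigureSpec:
    """Everything needed to draw one figure, with the layout precomputed.

    ``genes=None`` means no annotation was supplied and the gene panel is
    omitted; ``genes=[]`` draws the panel empty. ``y_max`` is the shared
    axis ceiling: the maximum value over all replicate tracks of all groups
    (1 when everything is zero).
    """

    region: GenomicRegion
    profiles: tuple[GroupProfile, ...]
    feature_tracks: tuple[FeatureTrack, ...] = ()
    genes: Optional[tuple[GeneModel, ...]] = None
    y_max: float = 1.0
    output_path: Union[str, Path] = "repviz.png"
    image_format: str = "png"

    @property
    def panel_count(self) -> int:
        return (
            len(self.profiles)
            + 1
            + (1 if self.feature_tracks else 0)
            + (1 if self.genes is not None else 0)
        )


def build_figure_spec(
    profiles: Sequence[GroupProfile],
    feature_tracks: Sequence[FeatureTrack] = (),
    genes: Optional[Sequence[GeneModel]] = None,
    region: Optional[GenomicRegion] = None,
    output_path: Union[str, Path] = "repviz.png",
    image_format: str = "png",
) -> FigureSpec:
    """Validate inputs and compute the shared y-scale.

    The ceiling is taken over *replicate* values across all groups; group
    means are bounded by replicate maxima so they always fit.
    """
    if not profiles:
        raise RenderError("cannot build a figure with no coverage groups")
    if image_format not in SUPPORTED_FORMATS:
        raise RenderError(
            f"unknown image format {image_format!r}; supported: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    if region is None:
        region = profiles[0].mean_track.region
    for prof in profiles:
        for track in prof.replicate_tracks:
            if track.region != region:
                raise RenderError(
                    f"track {track.sample_label!r} covers {track.region}, "
                    f"figure region is {region}"
                )
    y_max = max(
        (float(t.values.max()) for p in profiles for t in p.replicate_tracks if t.values.size),
        default=0.0,
    )
    if y_max <= 0:
        y_max = 1.0
    return FigureSpec(
        region=region,
        profiles=tuple(profiles),
        feature_tracks=tuple(feature_tracks),
        genes=None if genes is None else tuple(genes),
        y_max=y_max,
        output_path=output_path,
        image_format=image_format,
    )


def _bin_edges(track: CoverageTrack) -> np.ndarray:
    """x-positions of bin boundaries in 0-based genomic data coordinates."""
    n = track.values.size
    edges = track.region.start + np.minimum(
        np.arange(n + 1) * track.bin_size, track.region.length
    )
    return edges


def _group_color_offsets(profiles: Sequence[GroupProfile]) -> list[int]:
    offsets, total = [], 0
    for prof in profiles:
        offsets.append(total)
        total += len(prof.replicate_tracks)
    return offsets


def _feature_panel_rows(tracks: Sequence[FeatureTrack]) -> list[tuple[list[int], int]]:
    """Per track: the stack row of each feature and the row count (>= 1)."""
    out = []
    for ft in tracks:
        rows = assign_stack_rows([f.interval for f in ft.features])
        out.append((rows, (max(rows) + 1) if rows else 1))
    return out


def _draw_coverage_panel(ax, tracks, colors, y_max, title):
    for track, color in zip(tracks, colors):
        ax.stairs(
            track.values,
            _bin_edges(track),
            fill=True,
            color=color,
            alpha=0.45,
            linewidth=0.0,
            label=track.sample_label,
        )
        ax.stairs(track.values, _bin_edges(track), color=color, linewidth=0.7)
    ax.set_ylim(0.0, y_max)
    ax.set_ylabel(title, fontsize=8)
    ax.legend(loc="upper right", fontsize=6, frameon=False)


def _draw_average_panel(ax, profiles, offsets, y_max):
    for prof, off in zip(profiles, offsets):
        color = PALETTE[off % len(PALETTE)]
        track = prof.mean_track
        ax.stairs(track.values, _bin_edges(track), color=color, linewidth=1.4,
                  label=prof.group_name)
    ax.set_ylim(0.0, y_max)
    ax.set_ylabel("group means", fontsize=8)
    ax.legend(loc="upper right", fontsize=6, frameon=False)


def _draw_feature_panel(ax, tracks, per_track_rows):
    y_cursor = 0.0
    tick_pos, tick_labels = [], []
    for ft, (rows, n_rows) in zip(tracks, per_track_rows):
        for feat, row in zip(ft.features, rows):
            iv = feat.interval
            ax.add_patch(
                Rectangle(
                    (iv.start, y_cursor + row + 0.15),
                    iv.length,
                    0.7,
                    facecolor=_GLYPH_COLOR,
                    edgecolor="none",
                )
            )
        tick_pos.append(y_cursor + n_rows / 2.0)
        tick_labels.append(ft.label)
        y_cursor += n_rows + 0.5
    ax.set_yticks(tick_pos, tick_labels, fontsize=7)
    ax.set_ylim(y_cursor - 0.25, -0.25)  # inverted: first configured track on top
    ax.set_ylabel("features", fontsize=8)


def _draw_gene_panel(ax, genes: Sequence[GeneModel], region: GenomicRegion):
    ax.set_ylabel("genes", fontsize=8)
    ax.set_yticks([])
    visible = [(g, clip_interval(g.span, region)) for g in genes]
    visible = [(g, span) for g, span in visible if span is not None]
    if not visible:
        ax.set_ylim(-1.0, 1.0)
        return
    rows = assign_stack_rows([span for _, span in visible])
    for (gene, span), row in zip(visible, rows):
        y = -row * 1.6
        ax.plot([span.start, span.end], [y, y], color=_GLYPH_COLOR, linewidth=1.0)
        for exon in gene.exons:
            clipped = clip_interval(exon, region)
            if clipped is not None:
                ax.add_patch(
                    Rectangle(
                        (clipped.start, y - 0.32),
                        clipped.length,
                        0.64,
                        facecolor=_GLYPH_COLOR,
                        edgecolor="none",
                    )
                )
        if gene.strand in {"+", "-"}:
            marker = ">" if gene.strand == "+" else "<"
            xs = np.linspace(span.start, span.end, 8)[1:-1]
            ax.plot(
                xs, np.full(xs.size, y), linestyle="none", marker=marker,
                markersize=3.2, markerfacecolor="white",
                markeredgecolor=_GLYPH_COLOR, markeredgewidth=0.6,
            )
        ax.annotate(
            gene.gene_name, (span.start, y + 0.45), fontsize=7,
            annotation_clip=True, color=_GLYPH_COLOR,
        )
    ax.set_ylim(-(max(rows) * 1.6) - 1.0, 1.1)


def _set_genomic_xaxis(ax, region: GenomicRegion):
    """Tick labels in 1-based browser coordinates; data stays 0-based."""
    ticks_1based = MaxNLocator(nbins=6, steps=[1, 2, 2.5, 5, 10], integer=True).tick_values(
        region.start + 1, region.end
    )
    ticks_1based = [t for t in ticks_1based if region.start + 1 <= t <= region.end]
    ax.set_xticks([t - 1 for t in ticks_1based], [f"{int(t):,}" for t in ticks_1based],
                  fontsize=7)
    ax.set_xlabel(f"{region.chrom} position (bp)", fontsize=8)


def compose_figure(spec: FigureSpec) -> Figure:
    """Build the matplotlib Figure for a spec without writing it.

    Each axes carries a label (``coverage:<group>``, the average-panel
    sentinel, ``features``, ``genes``) so panels can be identified and their
    shared y-limits inspected programmatically before serialization.
    """
    region = spec.region
    offsets = _group_color_offsets(spec.profiles)
    per_track_rows = _feature_panel_rows(spec.feature_tracks)

    heights = [1.6] * (len(spec.profiles) + 1)
    if spec.feature_tracks:
        heights.append(0.3 * sum(n for _, n in per_track_rows) + 0.35)
    if spec.genes is not None:
        heights.append(1.0)

    fig = Figure(figsize=(9.0, sum(heights) + 0.8), layout="constrained")
    gs = fig.add_gridspec(len(heights), 1, height_ratios=heights)
    axes = gs.subplots(sharex=True)
    axes = np.atleast_1d(axes)

    idx = 0
    for prof, off in zip(spec.profiles, offsets):
        ax = axes[idx]
        ax.set_label(f"coverage:{prof.group_name}")
        colors = [
            PALETTE[(off + i) % len(PALETTE)]
            for i in range(len(prof.replicate_tracks))
        ]
        _draw_coverage_panel(ax, prof.replicate_tracks, colors, spec.y_max,
                             prof.group_name)
        idx += 1

    axes[idx].set_label(AVERAGE_PANEL_LABEL)
    _draw_average_panel(axes[idx], spec.profiles, offsets, spec.y_max)
    idx += 1

    if spec.feature_tracks:
        axes[idx].set_label("features")
        _draw_feature_panel(axes[idx], spec.feature_tracks, per_track_rows)
        idx += 1

    if spec.genes is not None:
        axes[idx].set_label("genes")
        _draw_gene_panel(axes[idx], spec.genes, region)
        idx += 1

    for ax in axes:
        ax.set_xlim(region.start, region.end)
        ax.tick_params(labelsize=7)
    _set_genomic_xaxis(axes[-1], region)
    fig.suptitle(str(region), fontsize=9)
    return fig


def render(spec: FigureSpec) -> Path:
    """Write the figure to ``spec.output_path`` in the requested format.

    The file is written atomically (temp file + rename) so a failure never
    leaves a partial image behind. SVG output is byte-deterministic.
    """
    if spec.image_format not in SUPPORTED_FORMATS:
        raise RenderError(
            f"unknown image format {spec.image_format!r}; supported: "
            + ", ".join(SUPPORTED_FORMATS)
        )
    out = Path(spec.output_path)
    tmp = out.with_name(out.name + ".part")
    # fixed hash salt + no date metadata => reproducible SVG/PDF bytes
    with mpl.rc_context({"svg.hashsalt": "repviz", "svg.fonttype": "none"}):
        fig = compose_figure(spec)
        metadata = None
        if spec.image_format == "svg":
            metadata = {"Date": None}
        elif spec.image_format == "pdf":
            metadata = {"CreationDate": None}
        try:
            fig.savefig(tmp, format=spec.image_format, dpi=150, metadata=metadata)
            os.replace(tmp, out)
        except OSError as exc:
            raise RenderError(f"cannot write figure to {out}: {exc}") from exc
        finally:
            tmp.unlink(missing_ok=True)
    return out
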