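# Methods

## Coordinate conventions

Everything internal is 0-based half-open, the convention BAM and BED use
natively. The two user-facing surfaces use 1-based inclusive browser
coordinates instead: the `CHROM:START-END` region string (thousands
separators accepted, because users paste from browsers) and the figure's
x-axis tick labels. GTF input (1-based inclusive) is converted at its
parser boundary. Each conversion happens in exactly one function, which is
the only reliable way to keep off-by-one drift out of a coordinate-heavy
codebase. Chromosome names are matched verbatim — no `chr1`/`1` aliasing —
because silent aliasing hides reference mismatches; a region chromosome
missing from a BAM header produces a warning plus an all-zero track rather
than an error, so files with partial contig sets can still be overlaid
while the mismatch stays visible in the log.

## Pileup depth

Depth at base *i* counts reads whose reference-consuming aligned CIGAR
operations (M, `=`, X) span *i*. D (deletion) and N (splice skip) advance
the reference cursor without adding depth; I, S, H, P never touch the
reference. This matches `samtools depth`-style pileup and keeps spliced
RNA-seq reads from painting introns, which matters when one figure mixes
data types. Depth is counted per *read*, not per fragment: no mate-pair
interval reconstruction is attempted (a possible extension, noted here
deliberately). Secondary, supplementary and unmapped records are always
excluded; duplicates are kept unless `exclude_duplicates` is set, on the
view that dedup policy belongs to the upstream pipeline, and `min_mapq`
defaults to 0. Counting uses vectorized slice increments over a numpy
array, one pass per read.

The implementation is verified against a deliberately naive oracle that
re-parses CIGAR strings with a regex and increments a counter base by base
in pure Python; agreement is exact integer equality on randomized read
sets that include S/I/D/N/`=`/X operations and secondary/supplementary/
duplicate/unmapped flag noise.

## Normalization and binning

Counts-per-million is the only supported scaling: values × 10⁶ / N, with
N the sample's mapped, primary, non-supplementary read count obtained by a
full scan of the file (a scan, not index statistics, because index counts
include secondary and supplementary records). Normalization is **off by
default** — the tool's premise is showing sequencing counts as they are,
with CPM available to *inspect* normalization behaviour (e.g. at
house-keeping loci). When enabled it is applied per sample, before group
averaging. Binning averages base-level values into `bin_size`-width bins,
the final partial bin over its actual width, so the width-weighted sum is
conserved exactly; it is never applied implicitly — large regions render
faster only when the user asks — keeping the drawn values reproducible.
The pipeline order is fixed: raw pileup → CPM (optional) → binning
(optional) → group mean.

## Group averaging

Each group's mean track is the elementwise arithmetic mean over that
group's own replicates, so groups of unequal size are first-class (a 5-vs-3
comparison needs no padding or subsetting). The mean is therefore bounded
by the replicate min/max envelope at every base, which is what lets every
coverage panel — means included — share one y-scale.

## Figure contract

Panel order is fixed: group panels in config order, the group-mean overlay,
the feature panel (present iff BED tracks were configured), the gene panel
(present iff an annotation was given; drawn empty when no gene overlaps).
The shared y-ceiling is the global maximum over all replicate values, or 1
when everything is zero. Coverage is drawn as translucent filled step
profiles (alpha 0.45) so overlapping replicates remain visible; colors come
from the 8-color Wong colorblind-safe palette assigned by global replicate
slot, cycling past eight, and a group's mean line reuses the color of the
group's first replicate slot so means stay attributable to groups. BED
features and gene spans are stacked by greedy first-fit in start order,
which for start-sorted intervals uses exactly the maximum overlap depth of
rows (interval-graph coloring optimality); feature-panel height grows with
the total stacked row count to avoid glyph collisions, while coverage
panels share equal heights. Gene models are flattened per gene (exon union
across transcripts) and drawn as exon boxes on a strand-arrowed line;
features and exons are clipped to the window so no glyph extends outside
it.

Rendering avoids pyplot entirely (a `matplotlib.figure.Figure` plus the
backend chosen by format), writes atomically via a temp file + rename so a
failure leaves no partial output, and pins `svg.hashsalt`, keeps SVG text
as text, and strips date metadata so identical inputs give byte-identical
SVG. SVG is the reference format for determinism checks; PNG and PDF are
for users (raster bytes are rasterizer-version-dependent and are not
guaranteed stable across matplotlib releases).

## Configuration files

The CSV contract is the minimal one: two positional columns
(`path,label`), no quoting, UTF-8; a first row whose second field is
`group`/`label` is treated as an accidental header and skipped. Paths
resolve relative to the CSV's directory so bundles are relocatable. The
same BAM may appear under several group labels — that is the supported way
to build multi-datatype layouts (each dataset as its own group). Existence
of every BAM, BAM index and BED is checked up front and all problems are
reported in one error, because a figure that fails after minutes of
coverage computation is hostile.

## Synthetic fixtures

The fixture generator exists so the whole pipeline is testable offline
with exactly known content. `write_bam` writes declarative read specs
(position, CIGAR, MAPQ, flags) to a coordinate-sorted indexed BAM with no
@PG or timestamp header lines, sorting in-process, so a fixed spec yields
byte-identical files. Unmapped reads are written *placed* (coordinate kept,
unmapped flag set) so region fetches actually encounter and must filter
them. Read sequences are constant `A`s: depth is sequence-agnostic.

`demo_scene` emulates a two-condition comparison at one focal peak:
5 + 5 replicates, each 150 background reads uniform over a 10 kb
chromosome plus 100 peak reads placed normally (σ = 110 bp) around the
peak center at 4 kb, read length 50; one control replicate gets 500 peak
reads instead — the "group mean driven by a single outlier" scenario. With
~250 reads per sample these library sizes are ~3 orders of magnitude below
real ChIP-seq experiments, chosen so the full suite and the acceptance
script run in seconds; the construction scales the *signal-to-background
geometry*, not the noise structure, of real data. What the generator does
not emulate: fragment-length distributions, GC and mappability bias,
realistic peak shapes beyond a Gaussian placement kernel, or duplicate
structure. Passing tests therefore demonstrate correctness of counting,
grouping, clipping and drawing — not robustness to real-data artifacts,
which live upstream of a visualization tool.

## Numerical and degenerate-input choices

- All-zero figures get a y-ceiling of 1 so axes stay drawable.
- An empty BED track still gets its labelled row (an empty track is
  information).
- Ties in stacking are broken by (start, end) sort order; identical inputs
  give identical row assignments and byte-identical output.
- `bin_size = 1` returns the input track object unchanged.
- CPM with a zero-read library is an error, not a NaN track.
- Region length 1 is legal; region length 0 is rejected at parse time.

## Known limitations

Read-level (not fragment-level) depth; CPM only (no RPKM/TMM/quantile);
GTF only (no GFF3); BED columns beyond the name are ignored; no bigWig
input; no Tn5 offset correction for ATAC-seq; one region per invocation;
static output only. Very large windows at `bin_size 1` are slow by design —
binning is the supported mitigation and is always explicit.
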