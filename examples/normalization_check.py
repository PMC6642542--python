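"""Inspecting library-size normalization with counts-per-million scaling.

Raw depth is confounded by sequencing depth: a replicate with twice the
reads looks twice as enriched everywhere. CPM scaling (1e6 / mapped
library size) removes that. This script prints raw vs CPM depth for each
demo replicate over the focal peak; the outlier replicate stays an outlier
after CPM because its enrichment is real, not a depth artifact.
"""

import tempfile
from pathlib import Path

from repviz import (
    GenomicRegion,
    compute_coverage,
    library_size,
    load_bam_config,
    normalize_track,
)
from repviz.fixtures import demo_scene

workdir = Path(tempfile.mkdtemp(prefix="repviz_example_"))
bundle = demo_scene(workdir, seed=1)
lo, hi = bundle.focal_peak
peak = GenomicRegion("chr1", lo, hi)

print(f"{'sample':<16s} {'lib size':>8s} {'raw mean':>9s} {'CPM mean':>9s}")
for group in load_bam_config(bundle.bam_config):
    for rec in group.samples:
        raw = compute_coverage(rec.bam_path, peak)
        lib = library_size(rec.bam_path)
        cpm = normalize_track(raw, lib)
        print(f"{rec.label:<16s} {lib:>8d} {raw.values.mean():>9.2f} "
              f"{cpm.values.mean():>9.1f}")
# CPM divides each sample by its own mapped-read total, so depth-driven
# differences shrink while genuine enrichment differences remain.
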