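# repviz

Replicate-driven visualization of genomic regions.

Sequencing assays such as ChIP-seq and ATAC-seq are analysed in groups of
biological replicates, but most genome browsers draw each sample as its own
track on its own scale, which makes two routine questions needlessly hard:
*do my replicates agree within a condition?* and *is a difference between
conditions real, or driven by one sample?* `repviz` answers both with a
single static snapshot of one locus:

- one coverage panel per group, all replicates color-coded and **every
  coverage panel on one shared vertical scale**;
- one panel overlaying each group's mean coverage;
- a stacked feature panel showing BED intervals (e.g. peak-caller or
  differential-peak-caller output), one labelled row per file;
- a gene-model panel from a GTF annotation.

Groups may have unequal sizes, and "groups" can just as well be different
data types (ATAC-seq vs ChIP-seq) over matched samples. The tool consumes
the standard outputs of an upstream pipeline — coordinate-sorted indexed
BAM, BED, GTF — and is driven by two small CSV files.

## The model

For sample *s* and reference base *i* in the window, depth is the pileup
count

&nbsp;&nbsp;&nbsp;&nbsp;c<sub>s</sub>(i) = #{reads of *s* whose aligned blocks (CIGAR M/=/X) cover *i*},

where deletions (D) and spliced skips (N) consume reference but add no
depth, and secondary/supplementary/unmapped records never count. The group
average panel shows the elementwise arithmetic mean over each group's own
replicates, x̄<sub>g</sub>(i) = (1/n<sub>g</sub>) Σ<sub>s∈g</sub> c<sub>s</sub>(i).
Optional counts-per-million scaling replaces c<sub>s</sub> by
c<sub>s</sub> · 10⁶/N<sub>s</sub>, with N<sub>s</sub> the sample's mapped,
primary, non-supplementary read count. Optional binning averages depth in
fixed-width bins (the last bin over its actual width). The shared axis
ceiling is max<sub>s,i</sub> c<sub>s</sub>(i) over *all* replicates of
*all* groups, so means (which never exceed replicate maxima) always fit.

## Usage

Two CSV files, two columns each, no header needed, paths relative to the
CSV itself:

```text
# bam_config.csv            # bed_config.csv (optional)
case_rep1.bam,case          macs2_peaks.bed,PC MACS2
case_rep2.bam,case          dp1.bed,DP1
control_rep1.bam,control    dp2.bed,DP2
```

```sh
repviz --region chr1:3,001-5,000 \
       --bam-config bam_config.csv \
       --bed-config bed_config.csv \
       --annotation annotation.gtf \
       --output figure.svg
```

Useful flags: `--normalize` (CPM), `--bin-size N` (fast rendering of large
windows), `--min-mapq Q`, `--exclude-duplicates`, `--format png|pdf|svg`.
Omitting `--bed-config` or `--annotation` drops the corresponding panel.

A complete synthetic input bundle is one command away:

```sh
repviz-fixtures demo --out demo_dir --seed 1
```

## Worked example

`python examples/render_demo_region.py` builds the demo bundle (two
conditions × five replicates; the third control replicate carries a ~5×
amplified focal peak) and renders the figure:

```text
region            : chr1:3001-5000 (2000 bp)
groups            : case (5 replicates), control (5 replicates)
feature tracks    : PC MACS2, DP1, DP2, DP3
genes in window   : DEMOB, DEMOA
shared y ceiling  : 101  (max depth over every replicate)
panel count       : 5
```

`python examples/coverage_and_averages.py` prints the numbers behind it:

```text
group 'case': mean depth over peak = 12.3
  ...
group 'control': mean depth over peak = 21.9
  control_rep1   aligned bases in peak = 4893
  control_rep2   aligned bases in peak = 5119
  control_rep3   aligned bases in peak = 23737
  control_rep4   aligned bases in peak = 5131
  control_rep5   aligned bases in peak = 4859
  median replicate total = 5119
```

The control mean is nearly double the case mean, yet the median control
replicate (5119) is indistinguishable from the case replicates — the gap is
driven entirely by `control_rep3`. That outlier signature is exactly what
the shared-scale replicate panels make visible at a glance, and what a
mean-only track would hide. The other examples demonstrate CPM
normalization inspection (`normalization_check.py`) and the track-loading
layer (`feature_and_gene_tracks.py`).

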