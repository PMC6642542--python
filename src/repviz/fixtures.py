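"""Synthetic BAM/BED/GTF generators with exactly known content.

Every generator is deterministic under a fixed seed and emits files valid
under their format standards, so the whole pipeline is testable offline.
Read sequences are arbitrary fixed bases — coverage depends only on
coordinates, CIGAR and flags. Fixture BAMs carry no @PG lines or
timestamps, and sorting happens in-process, so two runs with the same spec
produce byte-identical payloads.

:func:`demo_scene` builds a complete two-condition bundle — 5 + 5
replicates where the second condition's mean over a focal peak is driven by
a single ~5x amplified outlier replicate, plus a peak-caller-style BED,
three differential-caller-style BEDs, a toy gene annotation and both CSV
configs — the canonical end-to-end input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .errors import FixtureError

__all__ = [
    "ReadSpec",
    "FixtureSpec",
    "GeneSpec",
    "DemoBundle",
    "write_bam",
    "write_bed",
    "write_gtf",
    "random_fixture",
    "demo_scene",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")


@dataclass(frozen=True)
class ReadSpec:
    """Declarative description of one alignment record.

    ``pos`` is the 1-based leftmost aligned position (SAM convention).
    Unmapped reads are written as *placed* unmapped: they keep their
    coordinate but carry the unmapped flag and no CIGAR, so region fetches
    still see (and must filter) them.
    """

    chrom: str
    pos: int
    cigar: str
    mapq: int = 60
    secondary: bool = False
    supplementary: bool = False
    duplicate: bool = False
    unmapped: bool = False

    def __post_init__(self) -> None:
        if not _CIGAR_RE.findall(self.cigar) and not self.unmapped:
            raise FixtureError(f"unparsable CIGAR {self.cigar!r}")
        if not self.unmapped and self.reference_length < 1:
            raise FixtureError(
                f"CIGAR {self.cigar!r} consumes no reference; mapped reads must"
            )
        if not 0 <= self.mapq <= 60:
            raise FixtureError(f"mapq must be in [0, 60], got {self.mapq}")

    @property
    def query_length(self) -> int:
        return sum(int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in _QUERY_OPS)

    @property
    def reference_length(self) -> int:
        return sum(int(n) for n, op in _CIGAR_RE.findall(self.cigar) if op in _REF_OPS)

    @property
    def flag(self) -> int:
        return (
            (0x4 if self.unmapped else 0)
            | (0x100 if self.secondary else 0)
            | (0x400 if self.duplicate else 0)
            | (0x800 if self.supplementary else 0)
        )


@dataclass(frozen=True)
class FixtureSpec:
    """A reference dictionary plus the exact records a BAM should contain."""

    references: tuple[tuple[str, int], ...]
    reads: tuple[ReadSpec, ...] = ()

    def __post_init__(self) -> None:
        names = {n for n, _ in self.references}
        for read in self.reads:
            if read.chrom not in names:
                raise FixtureError(
                    f"read on {read.chrom!r} but reference list has only "
                    f"{sorted(names)}"
                )


def write_bam(spec: FixtureSpec, path: Union[str, Path]) -> Path:
    """Write a coordinate-sorted, indexed BAM containing exactly spec.reads.

    Sorting is done in-process (no external sort step and no @PG header
    line), so output bytes depend only on the spec.
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in spec.references],
    }
    tid = {name: i for i, (name, _) in enumerate(spec.references)}
    order = sorted(
        range(len(spec.reads)),
        key=lambda i: (tid[spec.reads[i].chrom], spec.reads[i].pos, i),
    )
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i in order:
            read = spec.reads[i]
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"read{i:05d}"
            seg.flag = read.flag
            seg.reference_id = tid[read.chrom]
            seg.reference_start = read.pos - 1
            if not read.unmapped:
                seg.cigarstring = read.cigar
                seg.mapping_quality = read.mapq
            qlen = max(read.query_length, 1) if not read.unmapped else 36
            seg.query_sequence = "A" * qlen
            seg.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(seg)
    pysam.index(str(path))
    return path


def write_bed(
    intervals: Sequence[tuple], path: Union[str, Path]
) -> Path:
    """Write (chrom, start, end[, name]) tuples as a tab-separated BED file.

    Coordinates are 0-based half-open, as in the BED standard. An empty
    list yields an empty (but loadable) file.
    """
    path = Path(path)
    lines = []
    for row in intervals:
        chrom, start, end = row[0], int(row[1]), int(row[2])
        if end <= start:
            raise FixtureError(f"BED interval end ({end}) must exceed start ({start})")
        fields = [str(chrom), str(start), str(end)]
        if len(row) > 3 and row[3] is not None:
            fields.append(str(row[3]))
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


@dataclass(frozen=True)
class GeneSpec:
    """Gene described in internal 0-based half-open coordinates."""

    chrom: str
    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-", "."}:
            raise FixtureError(f"invalid strand {self.strand!r}")
        for start, end in self.exons:
            if end <= start:
                raise FixtureError(f"exon end ({end}) must exceed start ({start})")


def write_gtf(genes: Sequence[GeneSpec], path: Union[str, Path]) -> Path:
    """Write an Ensembl-dialect GTF: one gene row plus exon rows per gene.

    Internal half-open exon coordinates are converted to GTF's 1-based
    inclusive convention on output.
    """
    path = Path(path)
    lines = []
    for gene in genes:
        name = gene.gene_name or gene.gene_id
        attrs = f'gene_id "{gene.gene_id}"; gene_name "{name}";'
        span_lo = min(s for s, _ in gene.exons) + 1
        span_hi = max(e for _, e in gene.exons)
        lines.append(
            f"{gene.chrom}\trepviz\tgene\t{span_lo}\t{span_hi}\t.\t{gene.strand}\t.\t{attrs}"
        )
        tx_attrs = attrs + f' transcript_id "{gene.gene_id}.t1";'
        for start, end in sorted(gene.exons):
            lines.append(
                f"{gene.chrom}\trepviz\texon\t{start + 1}\t{end}\t.\t{gene.strand}\t.\t{tx_attrs}"
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    return path


def _random_cigar(rng: np.random.Generator) -> str:
    parts = []
    if rng.random() < 0.3:
        parts.append(f"{int(rng.integers(1, 8))}S")
    n_blocks = int(rng.integers(1, 4))
    for b in range(n_blocks):
        if b:
            gap_op = rng.choice(["D", "N", "I"])
            gap_len = int(rng.integers(1, 40 if gap_op == "N" else 6))
            parts.append(f"{gap_len}{gap_op}")
        block_op = rng.choice(["M", "M", "M", "=", "X"])
        parts.append(f"{int(rng.integers(5, 40))}{block_op}")
    if rng.random() < 0.3:
        parts.append(f"{int(rng.integers(1, 8))}S")
    return "".join(parts)


def random_fixture(
    seed: int,
    n_reads: int = 200,
    chrom: str = "chr1",
    chrom_length: int = 2000,
) -> FixtureSpec:
    """Randomized read set with mixed CIGARs (S/I/D/N/=/X) and flag noise.

    Positions are uniform over the chromosome; ~5% of reads are secondary,
    ~3% supplementary, ~5% duplicates and ~2% placed-unmapped, so filtering
    rules are genuinely exercised. Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_reads):
        cigar = _random_cigar(rng)
        ref_len = sum(
            int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_OPS
        )
        pos = int(rng.integers(1, max(chrom_length - ref_len, 2)))
        reads.append(
            ReadSpec(
                chrom=chrom,
                pos=pos,
                cigar=cigar,
                mapq=int(rng.integers(0, 61)),
                secondary=bool(rng.random() < 0.05),
                supplementary=bool(rng.random() < 0.03),
                duplicate=bool(rng.random() < 0.05),
                unmapped=bool(rng.random() < 0.02),
            )
        )
    return FixtureSpec((( chrom, chrom_length),), tuple(reads))


@dataclass(frozen=True)
class DemoBundle:
    """Paths of everything :func:`demo_scene` wrote."""

    out_dir: Path
    bam_config: Path
    bed_config: Path
    annotation: Path
    region_text: str
    bam_paths: tuple[Path, ...]
    focal_peak: tuple[int, int]
    outlier_label: str


# demo scene geometry (0-based half-open, chromosome chr1 of 10 kb)
_DEMO_CHROM = ("chr1", 10_000)
_DEMO_PEAK = (3800, 4200)
_DEMO_REGION_TEXT = "chr1:3,001-5,000"
_READ_LEN = 50


def _demo_replicate_reads(
    rng: np.random.Generator, n_background: int, n_peak: int
) -> list[ReadSpec]:
    chrom, chrom_len = _DEMO_CHROM
    reads = []
    for _ in range(n_background):
        pos0 = int(rng.integers(0, chrom_len - _READ_LEN))
        reads.append(ReadSpec(chrom, pos0 + 1, f"{_READ_LEN}M",
                              mapq=int(rng.integers(20, 61))))
    center = (_DEMO_PEAK[0] + _DEMO_PEAK[1]) / 2.0
    for _ in range(n_peak):
        mid = float(np.clip(rng.normal(center, 110.0), 300, chrom_len - 300))
        pos0 = int(mid) - _READ_LEN // 2
        reads.append(ReadSpec(chrom, pos0 + 1, f"{_READ_LEN}M",
                              mapq=int(rng.integers(20, 61))))
    return reads


def demo_scene(out_dir: Union[str, Path], seed: int = 0) -> DemoBundle:
    """Write the full two-condition demo bundle into ``out_dir``.

    Conditions ``case`` and ``control`` each get 5 replicate BAMs of 150
    background reads plus peak reads over the focal peak; the third control
    replicate receives 5x the peak reads (500 vs 100), so the control mean
    over the peak is driven by that single outlier while the control median
    replicate stays comparable to the case replicates.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    rows: list[tuple[Path, str]] = []
    bam_paths = []
    outlier_label = "control_rep3"
    for group, prefix in (("case", "case_rep"), ("control", "control_rep")):
        for rep in range(1, 6):
            label = f"{prefix}{rep}"
            n_peak = 500 if label == outlier_label else 100
            spec = FixtureSpec(
                (_DEMO_CHROM,),
                tuple(_demo_replicate_reads(rng, n_background=150, n_peak=n_peak)),
            )
            bam = write_bam(spec, out_dir / f"{label}.bam")
            bam_paths.append(bam)
            rows.append((bam, group))

    lo, hi = _DEMO_PEAK
    write_bed([("chr1", lo - 100, hi + 100, "peak_1"), ("chr1", 6000, 6400, "peak_2")],
              out_dir / "macs2_peaks.bed")
    write_bed([("chr1", lo - 40, hi + 60, "dp_1")], out_dir / "dp1.bed")
    write_bed([("chr1", lo - 160, hi + 130, "dp_2")], out_dir / "dp2.bed")
    write_bed([("chr1", lo + 20, hi - 20, "dp_3")], out_dir / "dp3.bed")

    annotation = write_gtf(
        [
            GeneSpec("chr1", "GENE0001", "+", ((4400, 4700), (4900, 5300)),
                     gene_name="DEMOA"),
            GeneSpec("chr1", "GENE0002", "-", ((2200, 2500), (2800, 3100)),
                     gene_name="DEMOB"),
        ],
        out_dir / "annotation.gtf",
    )

    bam_config = out_dir / "bam_config.csv"
    bam_config.write_text(
        "\n".join(f"{p.name},{g}" for p, g in rows) + "\n", encoding="utf-8"
    )
    bed_config = out_dir / "bed_config.csv"
    bed_config.write_text(
        "macs2_peaks.bed,PC MACS2\ndp1.bed,DP1\ndp2.bed,DP2\ndp3.bed,DP3\n",
        encoding="utf-8",
    )

    return DemoBundle(
        out_dir=out_dir,
        bam_config=bam_config,
        bed_config=bed_config,
        annotation=annotation,
        region_text=_DEMO_REGION_TEXT,
        bam_paths=tuple(bam_paths),
        focal_peak=_DEMO_PEAK,
        outlier_label=outlier_label,
    )
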