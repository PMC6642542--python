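"""The two CSV configuration files that drive a visualization run.

Both files share one minimal dialect: two comma-separated columns, no
quoting, UTF-8. The BAM config maps alignment files to biological groups
(``<bam_path>,<group>``); the optional BED config lists feature tracks
(``<bed_path>,<label>``). A first line whose second field is literally
``group`` or ``label`` (case-insensitive) is treated as an accidental header
and skipped. Paths are resolved relative to the CSV file's own directory so
a config bundle can be moved around as a unit.

Validation is fail-fast and exhaustive: every missing BAM, index or BED in
a file is reported in a single error, before any coverage is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import ConfigError

__all__ = [
    "SampleRecord",
    "SampleGroup",
    "FeatureTrackConfig",
    "load_bam_config",
    "load_bed_config",
    "dump_bam_config",
    "dump_bed_config",
]

_HEADER_WORDS = {"group", "label"}


@dataclass(frozen=True)
class SampleRecord:
    """One BAM file bound to a named biological group."""

    bam_path: Path
    group: str

    @property
    def label(self) -> str:
        """Display name for the sample: the BAM file name without suffix."""
        return self.bam_path.stem


@dataclass(frozen=True)
class SampleGroup:
    """An ordered set of replicate samples sharing one group label.

    Groups may have unequal sizes; the order of samples is the CSV row
    order, which also fixes color assignment downstream.
    """

    name: str
    samples: tuple[SampleRecord, ...]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"group {self.name!r} has no samples")


@dataclass(frozen=True)
class FeatureTrackConfig:
    """One BED file plus the label of its track row in the figure."""

    bed_path: Path
    label: str


def _read_rows(path: Path, kind: str) -> list[tuple[str, str, int]]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot read {kind} config {path}: {exc}") from exc
    rows: list[tuple[str, str, int]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ConfigError(
                f"{path}:{lineno}: expected exactly two comma-separated fields "
                f"'<path>,<{kind} label>', got {line!r}"
            )
        if not rows and fields[1].lower() in _HEADER_WORDS:
            continue  # tolerated header row
        rows.append((fields[0], fields[1], lineno))
    if not rows:
        raise ConfigError(f"{path}: no data rows found")
    return rows


def bam_index_path(bam_path: Path) -> Optional[Path]:
    """Return the path of an existing BAM index, or None if absent."""
    for cand in (
        Path(str(bam_path) + ".bai"),
        bam_path.with_suffix(".bai"),
        Path(str(bam_path) + ".csi"),
    ):
        if cand.exists():
            return cand
    return None


def load_bam_config(path: Union[str, Path], validate: bool = True) -> list[SampleGroup]:
    """Parse the BAM config CSV into an ordered list of sample groups.

    Rows sharing a group label are collected into one group; group order is
    the order of first appearance, sample order within a group is row order.
    With ``validate`` (the default), all missing BAM files and missing
    indexes are collected and reported at once.
    """
    path = Path(path)
    rows = _read_rows(path, "group")
    base = path.parent
    grouped: dict[str, list[SampleRecord]] = {}
    for raw_path, group, _lineno in rows:
        bam = (base / raw_path).resolve() if not Path(raw_path).is_absolute() else Path(raw_path)
        grouped.setdefault(group, []).append(SampleRecord(bam, group))

    if validate:
        missing: list[str] = []
        for records in grouped.values():
            for rec in records:
                if not rec.bam_path.exists():
                    missing.append(f"missing BAM file: {rec.bam_path}")
                elif bam_index_path(rec.bam_path) is None:
                    missing.append(
                        f"missing BAM index for {rec.bam_path} "
                        f"(run: samtools index {rec.bam_path})"
                    )
        if missing:
            raise ConfigError(
                f"{path}: {len(missing)} unusable input(s):\n  " + "\n  ".join(missing)
            )

    return [SampleGroup(name, tuple(records)) for name, records in grouped.items()]


def load_bed_config(
    path: Union[str, Path, None], validate: bool = True
) -> list[FeatureTrackConfig]:
    """Parse the optional BED config CSV; an absent path yields an empty list."""
    if path is None:
        return []
    path = Path(path)
    rows = _read_rows(path, "label")
    base = path.parent
    configs = []
    for raw_path, label, _lineno in rows:
        bed = (base / raw_path).resolve() if not Path(raw_path).is_absolute() else Path(raw_path)
        configs.append(FeatureTrackConfig(bed, label))
    if validate:
        missing = [str(c.bed_path) for c in configs if not c.bed_path.exists()]
        if missing:
            raise ConfigError(
                f"{path}: missing BED file(s):\n  " + "\n  ".join(missing)
            )
    return configs


def _relpath(target: Path, base: Path) -> str:
    try:
        return str(target.relative_to(base))
    except ValueError:
        import os

        return os.path.relpath(target, base)


def dump_bam_config(groups: Sequence[SampleGroup], path: Union[str, Path]) -> Path:
    """Serialize groups back to CSV, with paths relative to the CSV's directory."""
    path = Path(path)
    base = path.parent.resolve()
    lines = [
        f"{_relpath(rec.bam_path, base)},{g.name}" for g in groups for rec in g.samples
    ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def dump_bed_config(configs: Sequence[FeatureTrackConfig], path: Union[str, Path]) -> Path:
    """Serialize feature-track configs back to CSV (relative paths)."""
    path = Path(path)
    base = path.parent.resolve()
    lines = [f"{_relpath(c.bed_path, base)},{c.label}" for c in configs]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
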