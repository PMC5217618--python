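"""Readers and writers for the formats the toolkit exchanges.

Covered formats: BED-style score tracks and BedGraph (0-based half-open),
a minimal subset of GEO SOFT sample files, tab-delimited sample metadata,
chromosome-size tables, call tables (TSV and BED5), and SAM/BAM alignments
reduced to binned read counts.

Score columns are parsed with a locale-independent decimal point; comma
decimals are rejected with a clear message rather than silently misread.
"""

from __future__ import annotations

import csv
import math
import os
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .core import (
    CnvCall,
    FormatError,
    Genome,
    GenomicInterval,
    Measurement,
    ProcessingRecord,
    SampleMeta,
    Segment,
    Track,
    ValidationError,
)

__all__ = [
    "ColumnMap",
    "BinnedCoverage",
    "read_bed_track",
    "write_track",
    "read_soft_sample",
    "coverage_from_alignments",
    "coverage_ratio_track",
    "read_sample_meta",
    "write_sample_meta",
    "read_genome_tsv",
    "write_genome_tsv",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_calls_tsv",
    "write_calls_tsv",
    "write_calls_bed",
]

_SKIP_PREFIXES = ("track", "browser", "#")


@dataclass(frozen=True)
class ColumnMap:
    """Where to find chrom/start/end/value in a delimited table.

    ``coordinate_base`` 1 means start positions are 1-based inclusive and are
    shifted down by one on import; 0 means coordinates are already half-open.
    """

    chrom_col: int = 0
    start_col: int = 1
    end_col: int = 2
    value_col: int = 3
    coordinate_base: int = 0
    header_rows: int = 0

    def __post_init__(self) -> None:
        cols = (self.chrom_col, self.start_col, self.end_col, self.value_col)
        if len(set(cols)) != 4:
            raise ValidationError("column indices must be distinct")
        if any(c < 0 for c in cols):
            raise ValidationError("column indices must be non-negative")
        if self.coordinate_base not in (0, 1):
            raise ValidationError("coordinate_base must be 0 or 1")

    @property
    def max_col(self) -> int:
        return max(self.chrom_col, self.start_col, self.end_col, self.value_col)


def _parse_value(text: str, where: str) -> float:
    if "," in text:
        raise FormatError(
            f"{where}: comma decimal {text!r} not supported; use a dot decimal point"
        )
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"{where}: non-numeric score {text!r}") from exc


def _parse_coord(text: str, where: str) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"{where}: malformed coordinate {text!r}") from exc


def _rows_to_measurements(
    rows: Iterable[tuple[int, Sequence[str]]],
    column_map: ColumnMap,
    source: str,
) -> list[Measurement]:
    """Shared field → Measurement conversion for BED-style and SOFT tables.

    ``rows`` yields (1-based line number, fields).  Lines whose score is NaN
    are skipped and reported via a warning; malformed fields raise.
    """
    measurements: list[Measurement] = []
    nan_lines: list[int] = []
    for lineno, fields in rows:
        where = f"{source}:{lineno}"
        if len(fields) <= column_map.max_col:
            raise FormatError(
                f"{where}: expected at least {column_map.max_col + 1} fields, got {len(fields)}"
            )
        value = _parse_value(fields[column_map.value_col], where)
        if math.isnan(value):
            nan_lines.append(lineno)
            continue
        start = _parse_coord(fields[column_map.start_col], where)
        end = _parse_coord(fields[column_map.end_col], where)
        if column_map.coordinate_base == 1:
            start -= 1
        try:
            interval = GenomicInterval(fields[column_map.chrom_col], start, end)
        except ValidationError as exc:
            raise FormatError(f"{where}: {exc}") from exc
        measurements.append(Measurement(interval, value))
    if nan_lines:
        warnings.warn(
            f"{source}: rejected {len(nan_lines)} line(s) with NaN score "
            f"(lines {', '.join(map(str, nan_lines[:10]))}"
            f"{'...' if len(nan_lines) > 10 else ''})"
        )
    return measurements


def read_bed_track(
    path: str | os.PathLike,
    column_map: ColumnMap | None = None,
    name: str | None = None,
    experiment_type: str = "log2ratio",
) -> Track:
    """Read a BED-style score track (``chromosome start stop score``).

    Lines starting with ``track``, ``browser`` or ``#`` are skipped, so plain
    BED, BedGraph and BED5 (with an appropriate ``column_map``) all parse.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)

    def rows():
        skipped_header = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith(_SKIP_PREFIXES):
                    continue
                if skipped_header < cmap.header_rows:
                    skipped_header += 1
                    continue
                yield lineno, line.split("\t")

    ms = _rows_to_measurements(rows(), cmap, str(path))
    return Track.build(name or path.stem, ms, experiment_type=experiment_type)


def _fmt(v: float) -> str:
    """Shortest decimal string that round-trips to the same float."""
    return repr(float(v))


def write_track(track: Track, path: str | os.PathLike, format: str = "bedgraph") -> None:
    """Write a track as BedGraph (4 columns + UCSC track line) or BED5.

    BED5 rows are ``chrom start end name score`` with ``name = track:index``
    and the measurement value in the score column at full precision.
    Ordering is the track's sorted measurement order, so output is stable.
    """
    if format not in ("bed", "bedgraph"):
        raise ValidationError(f"unknown track format {format!r}")
    with open(path, "w") as fh:
        if format == "bedgraph":
            fh.write(f'track type=bedGraph name="{track.name}"\n')
            for m in track.measurements:
                iv = m.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{_fmt(m.value)}\n")
        else:
            fh.write(f'track name="{track.name}"\n')
            for i, m in enumerate(track.measurements):
                iv = m.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{track.name}:{i}\t{_fmt(m.value)}\n"
                )


# ---------------------------------------------------------------------------
# GEO SOFT (minimal subset: one ^SAMPLE block with an embedded data table)

_POSITIONAL_ALIASES = {
    "chrom": {"chrom", "chromosome", "chr"},
    "start": {"start", "chrom_start", "range_start", "pos_start"},
    "end": {"end", "stop", "chrom_end", "range_end", "pos_end"},
    "value": {"value", "ratio", "log2ratio", "score", "signal"},
}


def read_soft_sample(
    path: str | os.PathLike,
    column_map: ColumnMap | None = None,
    platform: Mapping[str, tuple[str, int, int]] | None = None,
    name: str | None = None,
) -> Track:
    """Parse the data table of a single-sample GEO SOFT file into a track.

    Positional columns are located by name (CHROM/START/END/VALUE and common
    aliases) unless an explicit ``column_map`` over the table's columns is
    given.  Tables carrying only ID_REF/VALUE need a ``platform`` mapping of
    probe id to (chrom, start, end); without one a "platform required" error
    is raised.
    """
    path = Path(path)
    sample_id: str | None = None
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    in_table = False
    table_closed = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("^SAMPLE"):
                sample_id = line.split("=", 1)[1].strip() if "=" in line else None
            elif line.lower().startswith("!sample_table_begin"):
                in_table = True
            elif line.lower().startswith("!sample_table_end"):
                table_closed = True
                in_table = False
            elif in_table:
                if header is None:
                    header = line.split("\t")
                elif line.strip():
                    rows.append((lineno, line.split("\t")))
    if sample_id is None:
        raise FormatError(f"{path}: no ^SAMPLE block found")
    if header is None or not table_closed:
        raise FormatError(
            f"{path}: sample data table not delimited by "
            "!sample_table_begin/!sample_table_end"
        )

    if column_map is None:
        lower = [h.strip().lower() for h in header]
        found: dict[str, int] = {}
        for role, aliases in _POSITIONAL_ALIASES.items():
            for i, h in enumerate(lower):
                if h in aliases:
                    found[role] = i
                    break
        if len(found) == 4:
            column_map = ColumnMap(
                chrom_col=found["chrom"],
                start_col=found["start"],
                end_col=found["end"],
                value_col=found["value"],
            )
        elif platform is not None and "id_ref" in lower and "value" in found:
            id_col = lower.index("id_ref")
            val_col = found["value"]
            ms = []
            for lineno, fields in rows:
                probe = fields[id_col]
                if probe not in platform:
                    raise FormatError(f"{path}:{lineno}: probe {probe!r} not in platform table")
                chrom, start, end = platform[probe]
                value = _parse_value(fields[val_col], f"{path}:{lineno}")
                if math.isnan(value):
                    continue
                ms.append(Measurement(GenomicInterval(chrom, start, end), value))
            return Track.build(name or sample_id, ms)
        else:
            raise FormatError(
                f"{path}: table lacks positional columns (chrom/start/end); "
                "a platform position table is required to resolve probe ids"
            )

    ms = _rows_to_measurements(rows, column_map, str(path))
    return Track.build(name or sample_id, ms)


# ---------------------------------------------------------------------------
# SAM/BAM → binned coverage → log2-ratio track


@dataclass(frozen=True)
class BinnedCoverage:
    """Per-chromosome read counts on a fixed-width genome tiling."""

    genome: Genome
    bin_width: int
    counts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, length in self.genome:
            expected = -(-length // self.bin_width)  # ceil division
            got = len(self.counts[chrom])
            if got != expected:
                raise ValidationError(
                    f"{chrom}: expected {expected} bins, got {got}"
                )
            if np.any(np.asarray(self.counts[chrom]) < 0):
                raise ValidationError(f"{chrom}: negative bin count")

    @property
    def total(self) -> int:
        return int(sum(int(np.sum(c)) for c in self.counts.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))


def coverage_from_alignments(
    path: str | os.PathLike,
    genome: Genome,
    bin_width: int,
    min_mapq: int = 0,
) -> BinnedCoverage:
    """Count mapped primary alignments per fixed-width genomic bin.

    Each qualifying read increments the bin containing its leftmost aligned
    base (pysam's 0-based ``reference_start``).  Unmapped, secondary and
    supplementary alignments are skipped, as are reads below ``min_mapq``.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    counts = {
        chrom: np.zeros(-(-length // bin_width), dtype=np.int64)
        for chrom, length in genome
    }
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as af:
        offenders = [r for r in (af.references or ()) if r not in genome]
        if offenders:
            raise FormatError(
                f"{path}: chromosomes absent from genome: {', '.join(offenders)}"
            )
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            chrom = read.reference_name
            pos = read.reference_start
            idx = min(pos // bin_width, len(counts[chrom]) - 1)
            counts[chrom][idx] += 1
    return BinnedCoverage(genome=genome, bin_width=bin_width, counts=counts)


def coverage_ratio_track(
    test: BinnedCoverage,
    ref: BinnedCoverage,
    pseudocount: float = 1.0,
    name: str = "coverage_ratio",
) -> Track:
    """Library-size-normalized per-bin log2 ratio of two binned coverages.

    value = log2( ((t + p)/T) / ((r + p)/R) ) with T, R the total counts plus
    ``p`` per bin; bins where both raw counts are zero are omitted (no signal
    in either library says nothing about copy number).
    """
    if test.genome != ref.genome or test.bin_width != ref.bin_width:
        raise ValidationError("test and reference coverage must share genome and bin width")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    nbins = test.n_bins
    t_total = test.total + pseudocount * nbins
    r_total = ref.total + pseudocount * nbins
    ms: list[Measurement] = []
    for chrom, length in test.genome:
        tc = test.counts[chrom]
        rc = ref.counts[chrom]
        for i in range(len(tc)):
            if tc[i] == 0 and rc[i] == 0:
                continue
            value = math.log2(((tc[i] + pseudocount) / t_total) / ((rc[i] + pseudocount) / r_total))
            start = i * test.bin_width
            end = min(start + test.bin_width, length)
            ms.append(Measurement(GenomicInterval(chrom, start, end), value))
    history = (
        ProcessingRecord(
            operation="coverage_ratio",
            parameters={"pseudocount": pseudocount, "bin_width": test.bin_width},
            timestamp="",
            parent=name,
        ),
    )
    return Track.build(name, ms, experiment_type="ngs_log2ratio", history=history)


# ---------------------------------------------------------------------------
# Tabular metadata and interval lists


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    """Tab-delimited sample metadata; requires ``sample`` and ``group`` columns."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = [c.lower() for c in (reader.fieldnames or [])]
        for required in ("sample", "group"):
            if required not in cols:
                raise FormatError(f"{path}: missing required column {required!r}")
        out: list[SampleMeta] = []
        seen: set[str] = set()
        for row in reader:
            row = {k.lower(): v for k, v in row.items()}
            sample = row.pop("sample")
            group = row.pop("group")
            if sample in seen:
                raise FormatError(f"{path}: duplicate sample id {sample!r}")
            seen.add(sample)
            out.append(SampleMeta(sample=sample, group=group, extra=row))
    return out


def write_sample_meta(samples: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    extra_cols = sorted({k for s in samples for k in s.extra})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "group", *extra_cols])
        for s in samples:
            writer.writerow([s.sample, s.group, *[s.extra.get(k, "") for k in extra_cols]])


def read_genome_tsv(path: str | os.PathLike) -> Genome:
    """``chrom<TAB>length`` table, one chromosome per line, order preserved."""
    sizes: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes.append((fields[0], _parse_coord(fields[1], f"{path}:{lineno}")))
    return Genome(tuple(sizes))


def write_genome_tsv(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


def read_intervals_bed(path: str | os.PathLike) -> list[tuple[str, GenomicInterval]]:
    """Named intervals from BED (name in column 4; synthesized if absent)."""
    out: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected at least 3 BED fields")
            iv = GenomicInterval(
                fields[0],
                _parse_coord(fields[1], f"{path}:{lineno}"),
                _parse_coord(fields[2], f"{path}:{lineno}"),
            )
            name = fields[3] if len(fields) > 3 and fields[3] else str(iv)
            out.append((name, iv))
    return out


def write_intervals_bed(
    intervals: Sequence[tuple[str, GenomicInterval]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for name, iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# CNV call tables

_CALL_COLUMNS = ["sample", "chrom", "start", "end", "direction", "mean_value", "n_probes", "quality"]


def write_calls_tsv(calls: Sequence[CnvCall], path: str | os.PathLike) -> None:
    """Full-precision TSV of calls, one row per call."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for c in calls:
            s = c.segment
            writer.writerow(
                [
                    c.sample,
                    s.interval.chrom,
                    s.interval.start,
                    s.interval.end,
                    c.direction,
                    _fmt(s.mean_value),
                    s.n_probes,
                    "NA" if s.quality is None else _fmt(s.quality),
                ]
            )


def read_calls_tsv(path: str | os.PathLike) -> list[CnvCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _CALL_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        calls: list[CnvCall] = []
        for row in reader:
            seg = Segment(
                interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                mean_value=float(row["mean_value"]),
                n_probes=int(row["n_probes"]),
                quality=None if row["quality"] == "NA" else float(row["quality"]),
            )
            calls.append(CnvCall(segment=seg, direction=row["direction"], sample=row["sample"]))
    return calls


_SEGMENT_COLUMNS = ["chrom", "start", "end", "mean_value", "n_probes", "state"]


def write_segments_tsv(segments: Sequence[Segment], path: str | os.PathLike) -> None:
    """Full-precision TSV of segments (state column NA unless HMM-derived)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SEGMENT_COLUMNS)
        for s in segments:
            writer.writerow(
                [
                    s.interval.chrom,
                    s.interval.start,
                    s.interval.end,
                    _fmt(s.mean_value),
                    s.n_probes,
                    s.state if s.state is not None else "NA",
                ]
            )


def read_segments_tsv(path: str | os.PathLike) -> list[Segment]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _SEGMENT_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        return [
            Segment(
                interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                mean_value=float(row["mean_value"]),
                n_probes=int(row["n_probes"]),
                state=None if row["state"] == "NA" else row["state"],
            )
            for row in reader
        ]


def write_calls_bed(calls: Sequence[CnvCall], path: str | os.PathLike) -> None:
    """BED5 export of calls for browser display.

    name = ``sample|direction``; score = ``round(100 * |quality|)`` clamped to
    [0, 1000] (UCSC's score range), 0 when no quality is attached.  The TSV
    export keeps full precision; this file is for visualization only.
    """
    with open(path, "w") as fh:
        fh.write('track name="cnv_calls"\n')
        for c in calls:
            iv = c.segment.interval
            q = c.segment.quality
            score = 0 if q is None else min(1000, max(0, round(100 * abs(q))))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.sample}|{c.direction}\t{score}\n")
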