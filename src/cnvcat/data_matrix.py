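"""The common data matrix: heterogeneous tracks on a shared coordinate system.

Experiments from different platforms rarely share probe coordinates, so
direct column-wise comparison is impossible.  The fix is to re-express every
track on one binning scheme — fixed-width genomic bins, annotation intervals
such as genes, or custom intervals — and collect the per-bin aggregates into
a matrix with one row per bin and one column per track.

The cell statistic is the overlap-length-weighted mean of the measurements
touching the bin: each measurement contributes with weight equal to the
number of bases it shares with the bin, which is fair across platforms with
unequal probe lengths.  A bin no measurement touches is *missing* (exported
as ``NA``, never 0 — 0 is a meaningful log2 ratio).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    FormatError,
    Genome,
    GenomicInterval,
    Track,
    ValidationError,
    overlap_length,
)
from .interval_index import IntervalIndex

__all__ = [
    "BinningScheme",
    "DataMatrix",
    "make_bins",
    "map_track_to_bins",
    "build_matrix",
    "export_matrix",
    "read_matrix",
]

Bin = tuple[str, GenomicInterval]


@dataclass(frozen=True)
class BinningScheme:
    """How to partition the genome into matrix rows.

    ``fixed_width`` tiles every chromosome of ``genome`` into ``width``-bp
    bins (last bin truncated at the chromosome end).  ``annotation`` and
    ``custom`` pass through a list of named intervals (e.g. genes), sorted;
    nested or overlapping intervals are each scored independently.
    """

    mode: str
    width: int | None = None
    intervals: tuple[Bin, ...] | None = None
    genome: Genome | None = None

    def __post_init__(self) -> None:
        if self.mode == "fixed_width":
            if self.width is None or self.width <= 0:
                raise ValidationError("fixed_width binning requires width > 0")
            if self.genome is None:
                raise ValidationError("fixed_width binning requires a genome")
        elif self.mode in ("annotation", "custom"):
            if not self.intervals:
                raise ValidationError(f"{self.mode} binning requires a non-empty interval list")
            names = [n for n, _ in self.intervals]
            if len(set(names)) != len(names):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(f"duplicate interval names: {dupes}")
        else:
            raise ValidationError(f"unknown binning mode {self.mode!r}")


def make_bins(scheme: BinningScheme) -> list[Bin]:
    """Materialize the scheme's bins, sorted in genome order.

    Fixed-width bins are named ``chrom:start-end``; interval schemes keep the
    caller's names.  When a genome is attached, its chromosome order governs;
    otherwise chromosomes sort lexicographically.
    """
    if scheme.mode == "fixed_width":
        assert scheme.genome is not None and scheme.width is not None
        bins: list[Bin] = []
        for chrom, length in scheme.genome:
            for start in range(0, length, scheme.width):
                end = min(start + scheme.width, length)
                bins.append((f"{chrom}:{start}-{end}", GenomicInterval(chrom, start, end)))
        return bins
    assert scheme.intervals is not None
    if scheme.genome is not None:
        order = {c: i for i, c in enumerate(scheme.genome.chroms())}
        key = lambda b: (order.get(b[1].chrom, len(order)), b[1].chrom, b[1].start, b[1].end)
    else:
        key = lambda b: (b[1].chrom, b[1].start, b[1].end)
    return sorted(scheme.intervals, key=key)


def map_track_to_bins(track: Track, bins: Sequence[Bin]) -> list[tuple[str, float | None]]:
    """Overlap-weighted mean of the track per bin; ``None`` where nothing overlaps."""
    index = IntervalIndex((m.interval, m.value) for m in track.measurements)
    out: list[tuple[str, float | None]] = []
    for name, bin_iv in bins:
        hits = index.query(bin_iv)
        if not hits:
            out.append((name, None))
            continue
        wsum = 0.0
        vsum = 0.0
        for iv, value in hits:
            w = overlap_length(iv, bin_iv)
            wsum += w
            vsum += w * value
        out.append((name, vsum / wsum))
    return out


@dataclass(frozen=True)
class DataMatrix:
    """Rows = bins, columns = tracks, cells = aggregated values (NaN = missing)."""

    rows: tuple[Bin, ...]
    columns: tuple[str, ...]
    values: np.ndarray  # shape (n_rows, n_columns), float, NaN for missing

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.columns)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.rows)} rows x {len(self.columns)} columns"
            )

    def cell(self, row_name: str, column: str) -> float | None:
        i = [n for n, _ in self.rows].index(row_name)
        j = self.columns.index(column)
        v = self.values[i, j]
        return None if np.isnan(v) else float(v)


def build_matrix(tracks: Sequence[Track], scheme: BinningScheme) -> DataMatrix:
    """One column per track, mapped onto the scheme's bins in input order."""
    if not tracks:
        raise ValidationError("build_matrix requires at least one track")
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate track names")
    bins = make_bins(scheme)
    values = np.full((len(bins), len(tracks)), np.nan)
    for j, track in enumerate(tracks):
        for i, (_, v) in enumerate(map_track_to_bins(track, bins)):
            if v is not None:
                values[i, j] = v
    return DataMatrix(rows=tuple(bins), columns=tuple(names), values=values)


def export_matrix(matrix: DataMatrix, path: str | os.PathLike) -> None:
    """Tab-delimited export: row_name, chrom, start, end, then one column per track."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["row_name", "chrom", "start", "end", *matrix.columns])
        for (name, iv), row in zip(matrix.rows, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            writer.writerow([name, iv.chrom, iv.start, iv.end, *cells])


def read_matrix(path: str | os.PathLike) -> DataMatrix:
    """Parse a file written by :func:`export_matrix` back into a DataMatrix."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty matrix file") from None
        if header[:4] != ["row_name", "chrom", "start", "end"]:
            raise FormatError(f"{path}: unexpected matrix header {header[:4]}")
        columns = tuple(header[4:])
        rows: list[Bin] = []
        data: list[list[float]] = []
        for fields in reader:
            name, chrom, start, end = fields[:4]
            rows.append((name, GenomicInterval(chrom, int(start), int(end))))
            data.append([np.nan if c == "NA" else float(c) for c in fields[4:]])
    values = np.array(data) if data else np.empty((0, len(columns)))
    return DataMatrix(rows=tuple(rows), columns=columns, values=values)
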