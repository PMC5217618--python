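"""Region-of-interest summarization.

Each user-defined interval is split into exactly 10 equal-width sub-bins
(remainder bases go to the leftmost sub-bins) and summarized by the
overlap-weighted mean per sub-bin — the numeric substrate of a 10-cell
heatmap row.  Alongside, the interval's overall mean and sample SD are
computed over the *unweighted* values of all overlapping measurements (the
plain average of a probe list), and intervals are ranked by mean, gains
first by default.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import FormatError, GenomicInterval, Track, ValidationError, overlaps
from .data_matrix import map_track_to_bins

__all__ = ["N_SUB_BINS", "RoiSummary", "summarize_rois", "export_roi_table", "read_roi_table"]

N_SUB_BINS = 10


@dataclass(frozen=True)
class RoiSummary:
    """10-bin profile plus mean/SD/rank for one region of interest."""

    name: str
    interval: GenomicInterval
    sub_means: tuple[float | None, ...]
    mean: float | None
    sd: float | None
    rank: int

    def __post_init__(self) -> None:
        if len(self.sub_means) != N_SUB_BINS:
            raise ValidationError(f"expected {N_SUB_BINS} sub-bins, got {len(self.sub_means)}")


def split_interval(iv: GenomicInterval, n: int = N_SUB_BINS) -> list[GenomicInterval]:
    """Split into ``n`` half-open sub-bins whose widths differ by at most 1 bp.

    The ``length mod n`` remainder bases are distributed to the leftmost
    sub-bins, so widths are non-increasing and sum exactly to the width.
    """
    if iv.length < n:
        raise ValidationError(f"ROI {iv} is shorter than {n} bp; cannot form {n} sub-bins")
    base, rem = divmod(iv.length, n)
    out = []
    pos = iv.start
    for i in range(n):
        width = base + (1 if i < rem else 0)
        out.append(GenomicInterval(iv.chrom, pos, pos + width))
        pos += width
    return out


def summarize_rois(
    track: Track,
    rois: Sequence[tuple[str, GenomicInterval]],
    descending: bool = True,
) -> list[RoiSummary]:
    """Summarize a track over named ROIs, sorted and ranked by interval mean.

    Sub-bin values use the overlap-weighted rule shared with the data
    matrix; the interval mean/SD are unweighted over overlapping measurement
    values (SD with n−1 denominator, missing when fewer than 2 overlap).
    ROIs without any overlapping measurement sort last; ties are broken by
    (chrom, start).  Ranks are 1..n.
    """
    if not rois:
        raise ValidationError("summarize_rois requires at least one ROI")
    names = [n for n, _ in rois]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate ROI names")

    summaries = []
    for name, iv in rois:
        sub_bins = [(f"{name}/{i}", sub) for i, sub in enumerate(split_interval(iv))]
        sub_means = tuple(v for _, v in map_track_to_bins(track, sub_bins))
        vals = [m.value for m in track.measurements if overlaps(m.interval, iv)]
        mean = float(np.mean(vals)) if vals else None
        sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
        summaries.append((name, iv, sub_means, mean, sd))

    sign = -1.0 if descending else 1.0
    summaries.sort(
        key=lambda s: (
            math.inf if s[3] is None else sign * s[3],
            s[1].chrom,
            s[1].start,
        )
    )
    return [
        RoiSummary(name=n, interval=iv, sub_means=sm, mean=mean, sd=sd, rank=r)
        for r, (n, iv, sm, mean, sd) in enumerate(summaries, start=1)
    ]


def _cell(v: float | None) -> str:
    return "NA" if v is None else repr(float(v))


def export_roi_table(summaries: Sequence[RoiSummary], path: str | os.PathLike) -> None:
    """17-column TSV: name, coordinates, 10 sub-bin means, mean, sd, rank."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["name", "chrom", "start", "end"]
            + [f"bin{i + 1}" for i in range(N_SUB_BINS)]
            + ["mean", "sd", "rank"]
        )
        for s in summaries:
            writer.writerow(
                [s.name, s.interval.chrom, s.interval.start, s.interval.end]
                + [_cell(v) for v in s.sub_means]
                + [_cell(s.mean), _cell(s.sd), s.rank]
            )


def read_roi_table(path: str | os.PathLike) -> list[RoiSummary]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or len(header) != 4 + N_SUB_BINS + 3:
            raise FormatError(f"{path}: not an ROI summary table")
        out = []
        for fields in reader:
            sub = tuple(None if c == "NA" else float(c) for c in fields[4 : 4 + N_SUB_BINS])
            out.append(
                RoiSummary(
                    name=fields[0],
                    interval=GenomicInterval(fields[1], int(fields[2]), int(fields[3])),
                    sub_means=sub,
                    mean=None if fields[-3] == "NA" else float(fields[-3]),
                    sd=None if fields[-2] == "NA" else float(fields[-2]),
                    rank=int(fields[-1]),
                )
            )
    return out
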