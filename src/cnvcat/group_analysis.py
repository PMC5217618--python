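"""Cohort-level aberration tables: absolute counts and relative frequencies.

Recurrence of a CNV within a phenotype group — or a difference between
groups — is a key filter for biological relevance.  Two complementary views:

* the **absolute view** lists every call with its sample, group, direction,
  mean log2 ratio and quality score (the numbers behind a per-case plot);
* the **relative frequency** view counts, per genomic bin, per group and per
  direction, the *distinct samples* carrying at least one overlapping call,
  divided by the group size — a fraction in [0, 1] comparable across groups
  of different sizes.

A sample with several overlapping calls in a bin counts once; a sample with
both a gain and a loss in a bin contributes to both directions; samples with
no calls at all still count in the denominator.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import CnvCall, FormatError, GenomicInterval, SampleMeta, ValidationError, overlap_length
from .data_matrix import BinningScheme, make_bins
from .interval_index import IntervalIndex

__all__ = [
    "CohortCalls",
    "GroupFrequency",
    "absolute_view",
    "relative_frequency",
    "export_frequencies",
    "read_frequencies",
]

DIRECTIONS = ("gain", "loss")


@dataclass(frozen=True)
class CohortCalls:
    """Calls plus sample metadata for a set of phenotype groups.

    ``groups`` defaults to the order of first appearance in ``samples``.
    Every call must reference a known sample.
    """

    calls: tuple[CnvCall, ...]
    samples: tuple[SampleMeta, ...]
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [s.sample for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in cohort")
        if not self.groups:
            seen: list[str] = []
            for s in self.samples:
                if s.group not in seen:
                    seen.append(s.group)
            object.__setattr__(self, "groups", tuple(seen))
        known = set(ids)
        for c in self.calls:
            if c.sample not in known:
                raise ValidationError(f"call references unknown sample {c.sample!r}")
        by_group = self.group_sizes()
        for g in self.groups:
            if by_group.get(g, 0) == 0:
                raise ValidationError(f"group {g!r} has no samples")

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.samples:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes

    def group_of(self) -> dict[str, str]:
        return {s.sample: s.group for s in self.samples}


@dataclass(frozen=True)
class GroupFrequency:
    """Per-(bin, group, direction) sample count and group-size-relative fraction."""

    bin_name: str
    interval: GenomicInterval
    group: str
    direction: str
    n_samples_with_call: int
    group_size: int
    relative: float

    def __post_init__(self) -> None:
        if not 0 <= self.n_samples_with_call <= self.group_size:
            raise ValidationError("sample count must lie in [0, group_size]")
        if self.relative != self.n_samples_with_call / self.group_size:
            raise ValidationError("relative must equal n_samples_with_call / group_size")


def absolute_view(cohort: CohortCalls) -> pd.DataFrame:
    """One row per call — sample, group, coordinates, direction, ratio, quality.

    Sorted by (group, sample, chrom, start); the row multiset equals the call
    multiset (nothing merged, nothing dropped).
    """
    group_of = cohort.group_of()
    rows = [
        {
            "sample": c.sample,
            "group": group_of[c.sample],
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "direction": c.direction,
            "mean_value": c.segment.mean_value,
            "quality": c.segment.quality,
        }
        for c in cohort.calls
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample", "group", "chrom", "start", "end", "direction", "mean_value", "quality"],
    )
    return df.sort_values(["group", "sample", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )


def relative_frequency(
    cohort: CohortCalls,
    scheme: BinningScheme,
    min_overlap_frac: float = 0.0,
) -> list[GroupFrequency]:
    """Per-bin, per-group, per-direction aberration frequencies.

    A sample is counted in a bin when it has at least one call of the given
    direction overlapping the bin by at least 1 bp (or, with
    ``min_overlap_frac`` > 0, by at least that fraction of the call's
    length).  Records are emitted for every (group, direction) of every bin
    touched by at least one call; bins nobody touches are omitted — their
    frequencies are 0 by definition.
    """
    if not 0 <= min_overlap_frac <= 1:
        raise ValidationError("min_overlap_frac must be in [0, 1]")
    bins = make_bins(scheme)
    group_of = cohort.group_of()
    sizes = cohort.group_sizes()
    index = IntervalIndex(
        (c.interval, (group_of[c.sample], c.direction, c.sample, c.interval))
        for c in cohort.calls
    )
    out: list[GroupFrequency] = []
    for name, bin_iv in bins:
        hits = index.query(bin_iv)
        if not hits:
            continue
        members: dict[tuple[str, str], set[str]] = {}
        for _, (group, direction, sample, call_iv) in hits:
            needed = max(1, min_overlap_frac * call_iv.length)
            if overlap_length(call_iv, bin_iv) >= needed:
                members.setdefault((group, direction), set()).add(sample)
        if not members:
            continue
        for group in cohort.groups:
            for direction in DIRECTIONS:
                n = len(members.get((group, direction), ()))
                size = sizes[group]
                out.append(
                    GroupFrequency(
                        bin_name=name,
                        interval=bin_iv,
                        group=group,
                        direction=direction,
                        n_samples_with_call=n,
                        group_size=size,
                        relative=n / size,
                    )
                )
    return out


_FREQ_COLUMNS = ["bin_name", "chrom", "start", "end", "group", "direction", "n", "group_size", "relative"]


def export_frequencies(freqs: Sequence[GroupFrequency], path: str | os.PathLike) -> None:
    """RFC-4180 CSV, ordered genome → group → gain-before-loss as produced."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\r\n")
        writer.writerow(_FREQ_COLUMNS)
        for f in freqs:
            writer.writerow(
                [
                    f.bin_name,
                    f.interval.chrom,
                    f.interval.start,
                    f.interval.end,
                    f.group,
                    f.direction,
                    f.n_samples_with_call,
                    f.group_size,
                    repr(float(f.relative)),
                ]
            )


def read_frequencies(path: str | os.PathLike) -> list[GroupFrequency]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _FREQ_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        out = []
        for row in reader:
            out.append(
                GroupFrequency(
                    bin_name=row["bin_name"],
                    interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
                    group=row["group"],
                    direction=row["direction"],
                    n_samples_with_call=int(row["n"]),
                    group_size=int(row["group_size"]),
                    relative=float(row["relative"]),
                )
            )
    return out
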