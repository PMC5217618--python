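"""Domain types shared by every module of the toolkit.

Coordinate convention
---------------------
All in-memory coordinates are 0-based half-open (the BED convention):
an interval ``chr1:[0, 100)`` covers the first 100 bases of chr1 and abuts,
without overlapping, ``chr1:[100, 200)``.  Readers for 1-based formats
(SAM POS) shift at the boundary; nothing downstream ever sees 1-based
coordinates.

Chromosome names are matched verbatim — ``chr1`` and ``1`` are different
chromosomes.  Silent renaming corrupts joins across tracks, so any aliasing
must happen explicitly at import time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Any, Iterable, Mapping

import numpy as np

__all__ = [
    "CnvcatError",
    "FormatError",
    "ValidationError",
    "DegenerateNoiseError",
    "GenomicInterval",
    "Measurement",
    "ProcessingRecord",
    "Track",
    "Segment",
    "CnvCall",
    "SampleMeta",
    "Genome",
    "overlaps",
    "overlap_length",
    "record_step",
]


class CnvcatError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CnvcatError):
    """A file could not be parsed as the declared format."""


class ValidationError(CnvcatError):
    """An in-memory object violates a domain invariant."""


class DegenerateNoiseError(CnvcatError):
    """Noise estimate (MAD) is zero, so noise-relative quantities are undefined."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open span ``[start, end)`` in base pairs.

    ``start`` is 0-based inclusive, ``end`` exclusive.  Zero-length intervals
    are rejected: no measurement can anchor to an empty span.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by the two intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Measurement:
    """One interval-anchored value: a log2 ratio or an experiment score."""

    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValidationError(f"non-finite measurement value at {self.interval}")


@dataclass(frozen=True)
class ProcessingRecord:
    """One step of a track's processing history.

    The ``parameters`` mapping must fully reconstruct the call; it is
    serialized to JSON, so values must be JSON-representable.
    """

    operation: str
    parameters: Mapping[str, Any]
    timestamp: str
    parent: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "operation": self.operation,
                "parameters": dict(self.parameters),
                "timestamp": self.timestamp,
                "parent": self.parent,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProcessingRecord":
        d = json.loads(text)
        return cls(
            operation=d["operation"],
            parameters=d["parameters"],
            timestamp=d["timestamp"],
            parent=d["parent"],
        )


def _measurement_key(m: Measurement) -> tuple[str, int, int]:
    return (m.interval.chrom, m.interval.start, m.interval.end)


@dataclass(frozen=True)
class Track:
    """An ordered per-sample sequence of measurements plus its processing history.

    Measurements are kept sorted by (chrom, start, end); use :meth:`build`
    to construct a track from unsorted input.  Tracks are immutable —
    every transform returns a new track, typically with one more
    :class:`ProcessingRecord` appended (see :func:`record_step`).
    """

    name: str
    experiment_type: str = "log2ratio"
    measurements: tuple[Measurement, ...] = ()
    history: tuple[ProcessingRecord, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("track name must be non-empty")
        keys = [_measurement_key(m) for m in self.measurements]
        if any(b < a for a, b in zip(keys, keys[1:])):
            raise ValidationError(f"track {self.name!r}: measurements not sorted")

    @classmethod
    def build(
        cls,
        name: str,
        measurements: Iterable[Measurement],
        experiment_type: str = "log2ratio",
        history: tuple[ProcessingRecord, ...] = (),
    ) -> "Track":
        ms = tuple(sorted(measurements, key=_measurement_key))
        return cls(name=name, experiment_type=experiment_type, measurements=ms, history=history)

    def __len__(self) -> int:
        return len(self.measurements)

    def values(self) -> np.ndarray:
        return np.array([m.value for m in self.measurements], dtype=float)

    def by_chrom(self) -> dict[str, list[Measurement]]:
        """Measurements grouped by chromosome, preserving sorted order."""
        out: dict[str, list[Measurement]] = {}
        for m in self.measurements:
            out.setdefault(m.interval.chrom, []).append(m)
        return out


def record_step(
    track: Track, operation: str, parameters: Mapping[str, Any]
) -> Track:
    """Return ``track`` with one more history record; the input is unmodified."""
    rec = ProcessingRecord(
        operation=operation,
        parameters=dict(parameters),
        timestamp=datetime.now(timezone.utc).isoformat(),
        parent=track.name,
    )
    return replace(track, history=track.history + (rec,))


@dataclass(frozen=True)
class Segment:
    """A contiguous run of probes with a common mean.

    ``interval`` spans from the first to the last member probe.  ``quality``
    is filled in by the scoring step; ``state`` carries the HMM state label
    (``loss``/``neutral``/``gain``) when the segment came from HMM decoding.
    """

    interval: GenomicInterval
    mean_value: float
    n_probes: int
    quality: float | None = None
    state: str | None = None

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError("segment must contain at least one probe")


@dataclass(frozen=True)
class CnvCall:
    """A gain or loss call attributed to a sample."""

    segment: Segment
    direction: str
    sample: str

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValidationError(f"direction must be gain or loss, got {self.direction!r}")
        if self.direction == "gain" and self.segment.mean_value <= 0:
            raise ValidationError("gain call requires positive segment mean")
        if self.direction == "loss" and self.segment.mean_value >= 0:
            raise ValidationError("loss call requires negative segment mean")

    @property
    def interval(self) -> GenomicInterval:
        return self.segment.interval


@dataclass(frozen=True)
class SampleMeta:
    """Sample id plus phenotype/group label and free-form extra attributes."""

    sample: str
    group: str
    extra: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome-name → length table.

    The ordering is stable and is used for every genome-wide output
    (bin tiling, matrix rows, frequency exports).
    """

    chrom_sizes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chrom_sizes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in genome")
        for c, length in self.chrom_sizes:
            if length <= 0:
                raise ValidationError(f"chromosome {c!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "Genome":
        return cls(tuple(sizes.items()))

    def chroms(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chrom_sizes)

    def length(self, chrom: str) -> int:
        for c, length in self.chrom_sizes:
            if c == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chrom_sizes)

    def __iter__(self):
        return iter(self.chrom_sizes)
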