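"""Deterministic synthetic-data generators for every input the toolkit consumes.

These generators are first-class: they define the study conditions under
which the calling machinery is exercised.  Each takes an explicit seed and
is bit-reproducible; each returns ground truth alongside the data so
recovery can be checked against what was actually planted, never against a
re-run.

What is emulated: evenly spaced aCGH-style probes with additive Gaussian
noise and step-shaped CNV events; cohorts of samples sharing group-specific
events plus Poisson-distributed private events; single-end SAM alignments
placed by an inhomogeneous rate along the genome.  What is not: GC/wave
artifacts, probe-specific variance, sequencing errors, paired ends.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    CnvCall,
    Genome,
    GenomicInterval,
    Measurement,
    SampleMeta,
    Segment,
    Track,
    ValidationError,
    overlaps,
)
from .group_analysis import CohortCalls
from .io_formats import write_calls_tsv, write_sample_meta

__all__ = ["ProfileSpec", "make_acgh_track", "make_cohort", "make_sam_fixture"]

Event = tuple[GenomicInterval, float]


@dataclass(frozen=True)
class ProfileSpec:
    """Recipe for one synthetic aCGH log2-ratio profile.

    ``cnv_events`` is a list of (interval, true log2 shift); events must lie
    within chromosome bounds and must not overlap each other, so the planted
    truth stays unambiguous.  ``noise_sd`` is the SD of the additive Gaussian
    probe noise (0.1–0.2 is typical for aCGH; 0 gives a noiseless profile).
    """

    genome: Genome
    n_probes_per_chrom: int = 100
    cnv_events: tuple[Event, ...] = ()
    noise_sd: float = 0.15
    seed: int = 0
    probe_width: int = 60

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_probes_per_chrom < 1:
            raise ValidationError("need at least one probe per chromosome")
        for iv, shift in self.cnv_events:
            if iv.chrom not in self.genome:
                raise ValidationError(f"event chromosome {iv.chrom!r} not in genome")
            if iv.end > self.genome.length(iv.chrom):
                raise ValidationError(f"event {iv} extends past chromosome end")
            if shift == 0:
                raise ValidationError(f"event {iv} has zero shift")
        for i, (a, _) in enumerate(self.cnv_events):
            for b, _ in self.cnv_events[i + 1 :]:
                if overlaps(a, b):
                    raise ValidationError(f"events {a} and {b} overlap; truth would be ambiguous")


def _probe_intervals(spec: ProfileSpec, chrom: str, length: int) -> list[GenomicInterval]:
    spacing = max(1, length // spec.n_probes_per_chrom)
    out = []
    for i in range(spec.n_probes_per_chrom):
        start = i * spacing
        if start >= length:
            break
        end = min(start + min(spec.probe_width, spacing), length)
        out.append(GenomicInterval(chrom, start, end))
    return out


def make_acgh_track(spec: ProfileSpec, name: str = "synthetic") -> tuple[Track, list[CnvCall]]:
    """Generate a probe track plus the ground-truth calls implied by its events.

    Probe value = sum of shifts of events overlapping the probe + N(0, sd).
    Each event's truth call spans its first to last member probe with
    mean_value equal to the planted shift.
    """
    rng = np.random.default_rng(spec.seed)
    measurements: list[Measurement] = []
    truth: list[CnvCall] = []
    for chrom, length in spec.genome:
        probes = _probe_intervals(spec, chrom, length)
        noise = rng.normal(0.0, spec.noise_sd, size=len(probes)) if spec.noise_sd > 0 else np.zeros(len(probes))
        shifts = np.zeros(len(probes))
        for iv, shift in spec.cnv_events:
            if iv.chrom != chrom:
                continue
            member = [i for i, p in enumerate(probes) if overlaps(p, iv)]
            for i in member:
                shifts[i] += shift
            if member:
                span = GenomicInterval(chrom, probes[member[0]].start, probes[member[-1]].end)
                seg = Segment(interval=span, mean_value=shift, n_probes=len(member))
                truth.append(
                    CnvCall(segment=seg, direction="gain" if shift > 0 else "loss", sample=name)
                )
        measurements.extend(
            Measurement(p, float(shifts[i] + noise[i])) for i, p in enumerate(probes)
        )
    return Track.build(name, measurements), truth


def make_cohort(
    n_per_group: Mapping[str, int],
    shared_events: Mapping[str, Sequence[Event]],
    private_event_rate: float,
    genome: Genome,
    seed: int = 0,
    noise_sd: float = 0.15,
    out_dir: str | os.PathLike | None = None,
    private_event_width: int = 500_000,
    private_event_shift: float = 0.8,
) -> tuple[CohortCalls, dict[str, list[CnvCall]]]:
    """Generate a multi-group cohort of CNV calls plus metadata.

    Every sample of a group carries all of the group's ``shared_events``
    (probability 1), plus ``Poisson(private_event_rate)`` private events at
    uniform random positions, each a gain or loss of magnitude
    ``private_event_shift`` with equal probability.  Quality scores are set
    to shift/noise_sd, the planted signal-to-noise.

    Returns the cohort and the per-sample ground truth of *shared* events
    only (private events are noise from the comparison's point of view).
    If ``out_dir`` is given, writes ``calls.tsv`` and ``samples.tsv`` there.
    """
    if not n_per_group:
        raise ValidationError("cohort needs at least one group")
    for g, n in n_per_group.items():
        if n < 1:
            raise ValidationError(f"group {g!r} must have at least one sample")
    if private_event_rate < 0:
        raise ValidationError("private_event_rate must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = genome.chroms()
    samples: list[SampleMeta] = []
    calls: list[CnvCall] = []
    truth: dict[str, list[CnvCall]] = {}
    for group in n_per_group:
        events = tuple(shared_events.get(group, ()))
        for i in range(n_per_group[group]):
            sid = f"{group}_{i + 1:03d}"
            samples.append(SampleMeta(sample=sid, group=group))
            truth[sid] = []
            for iv, shift in events:
                seg = Segment(
                    interval=iv,
                    mean_value=shift,
                    n_probes=max(1, iv.length // 10_000),
                    quality=shift / noise_sd if noise_sd > 0 else None,
                )
                call = CnvCall(
                    segment=seg, direction="gain" if shift > 0 else "loss", sample=sid
                )
                calls.append(call)
                truth[sid].append(call)
            for _ in range(rng.poisson(private_event_rate)):
                chrom = chroms[rng.integers(len(chroms))]
                length = genome.length(chrom)
                width = min(private_event_width, length)
                start = int(rng.integers(0, max(1, length - width + 1)))
                shift = float(private_event_shift * (1 if rng.random() < 0.5 else -1))
                seg = Segment(
                    interval=GenomicInterval(chrom, start, start + width),
                    mean_value=shift,
                    n_probes=max(1, width // 10_000),
                    quality=shift / noise_sd if noise_sd > 0 else None,
                )
                calls.append(
                    CnvCall(segment=seg, direction="gain" if shift > 0 else "loss", sample=sid)
                )
    cohort = CohortCalls(calls=tuple(calls), samples=tuple(samples))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_calls_tsv(cohort.calls, os.path.join(out_dir, "calls.tsv"))
        write_sample_meta(cohort.samples, os.path.join(out_dir, "samples.tsv"))
    return cohort, truth


def make_sam_fixture(
    genome: Genome,
    n_reads: int,
    enrichment: Sequence[Event] = (),
    seed: int = 0,
    path: str | os.PathLike | None = None,
    read_length: int = 50,
) -> str:
    """Plain-text SAM with single-end reads placed by an inhomogeneous rate.

    The base placement rate is uniform (1 per bp); within each ``enrichment``
    interval it is multiplied by the given factor (> 0).  Read start positions
    are drawn from the resulting piecewise-constant density, clipped so the
    whole read fits its chromosome.  Reads are flag 0, MAPQ 60, CIGAR
    ``<len>M``.  Returns the SAM text; also writes it when ``path`` is given.
    """
    for iv, rate in enrichment:
        if rate <= 0:
            raise ValidationError(f"enrichment rate for {iv} must be > 0")
        if iv.chrom not in genome:
            raise ValidationError(f"enrichment chromosome {iv.chrom!r} not in genome")
    rng = np.random.default_rng(seed)

    # piecewise-constant segments (chrom, start, end, rate) covering the genome
    pieces: list[tuple[str, int, int, float]] = []
    for chrom, length in genome:
        edges = {0, length}
        for iv, _ in enrichment:
            if iv.chrom == chrom:
                edges.update((max(0, iv.start), min(length, iv.end)))
        cuts = sorted(edges)
        for lo, hi in zip(cuts, cuts[1:]):
            rate = 1.0
            for iv, mult in enrichment:
                if iv.chrom == chrom and iv.start <= lo and hi <= iv.end:
                    rate *= mult
            pieces.append((chrom, lo, hi, rate))

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in genome:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")

    if n_reads > 0:
        weights = np.array([(hi - lo) * rate for _, lo, hi, rate in pieces], dtype=float)
        probs = weights / weights.sum()
        choices = rng.choice(len(pieces), size=n_reads, p=probs)
        offsets = rng.random(n_reads)
        for r, (c, u) in enumerate(zip(choices, offsets)):
            chrom, lo, hi, _ = pieces[c]
            pos = lo + int(u * (hi - lo))
            pos = min(pos, genome.length(chrom) - read_length)
            pos = max(pos, 0)
            seq = "A" * read_length
            lines.append(
                f"read{r}\t0\t{chrom}\t{pos + 1}\t60\t{read_length}M\t*\t0\t0\t{seq}\t*"
            )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
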