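"""File-based project layout — the persistence layer.

A project is a directory::

    project/
      tracks/    one BedGraph file per track
      calls/     one BED file per call set (plus a full-precision TSV)
      meta/samples.tsv
      meta/genome.tsv        chrom<TAB>length
      history/   one JSON-lines file per track (ProcessingRecords)

Everything is plain text, diffable and directly loadable into a genome
browser.
"""

from __future__ import annotations

import os
from dataclasses import replace
from pathlib import Path
from typing import Sequence

from .core import CnvCall, Genome, ProcessingRecord, SampleMeta, Track
from .io_formats import (
    read_bed_track,
    read_genome_tsv,
    read_sample_meta,
    write_calls_bed,
    write_calls_tsv,
    write_genome_tsv,
    write_sample_meta,
    write_track,
)

__all__ = ["Project"]


class Project:
    """Handle to a project directory; creates the layout on first use."""

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)
        for sub in ("tracks", "calls", "meta", "history"):
            (self.root / sub).mkdir(parents=True, exist_ok=True)

    # -- tracks -------------------------------------------------------------
    def save_track(self, track: Track) -> Path:
        path = self.root / "tracks" / f"{track.name}.bedgraph"
        write_track(track, path, format="bedgraph")
        hist = self.root / "history" / f"{track.name}.jsonl"
        with open(hist, "w") as fh:
            for rec in track.history:
                fh.write(rec.to_json() + "\n")
        return path

    def load_track(self, name: str) -> Track:
        track = read_bed_track(self.root / "tracks" / f"{name}.bedgraph", name=name)
        hist_path = self.root / "history" / f"{name}.jsonl"
        if hist_path.exists():
            with open(hist_path) as fh:
                records = tuple(ProcessingRecord.from_json(line) for line in fh if line.strip())
            track = replace(track, history=records)
        return track

    def track_names(self) -> list[str]:
        return sorted(p.stem for p in (self.root / "tracks").glob("*.bedgraph"))

    # -- calls --------------------------------------------------------------
    def save_calls(self, calls: Sequence[CnvCall], name: str) -> Path:
        write_calls_bed(calls, self.root / "calls" / f"{name}.bed")
        path = self.root / "calls" / f"{name}.tsv"
        write_calls_tsv(calls, path)
        return path

    # -- metadata -----------------------------------------------------------
    def save_genome(self, genome: Genome) -> None:
        write_genome_tsv(genome, self.root / "meta" / "genome.tsv")

    def load_genome(self) -> Genome:
        return read_genome_tsv(self.root / "meta" / "genome.tsv")

    def save_samples(self, samples: Sequence[SampleMeta]) -> None:
        write_sample_meta(samples, self.root / "meta" / "samples.tsv")

    def load_samples(self) -> list[SampleMeta]:
        return read_sample_meta(self.root / "meta" / "samples.tsv")
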