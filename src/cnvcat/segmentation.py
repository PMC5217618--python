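"""CNV calling on log2-ratio tracks.

Four cooperating pieces:

* **Noise estimation** — the raw median absolute deviation (MAD, no 1.4826
  consistency factor) of probe values around the track median, or, when a
  segmentation has already been computed, around each probe's segment mean
  (the residual MAD).  The raw MAD is deliberate: the quality score below is
  defined directly in MAD units.
* **Threshold calling** — maximal runs of consecutive probes beyond a fixed
  or dynamic (median ± k·MAD) threshold become gain/loss calls.
* **Segmentation** — circular binary segmentation (CBS) with a permutation
  test for split significance, and a 3-state Gaussian-emission HMM decoded
  exactly by Viterbi.  Both treat probes as an ordered sequence within each
  chromosome; inter-probe distance is ignored.
* **Quality scoring** — segment mean divided by the MAD: a robust
  signal-to-noise ratio, positive for gains, negative for losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    CnvCall,
    DegenerateNoiseError,
    GenomicInterval,
    Measurement,
    Segment,
    Track,
    ValidationError,
)

__all__ = [
    "ThresholdSpec",
    "NoiseEstimate",
    "CbsParams",
    "HmmParams",
    "HMM_STATES",
    "estimate_noise",
    "call_thresholds",
    "cbs_segment",
    "max_arc_statistic",
    "hmm_segment",
    "viterbi_path",
    "quality_score",
    "calls_from_segments",
]


@dataclass(frozen=True)
class ThresholdSpec:
    """Gain/loss thresholds on the log2-ratio scale.

    ``fixed`` mode uses ``upper``/``lower`` verbatim; ``dynamic`` mode derives
    them from the data as median ± k·MAD (raw MAD).  ``min_probes`` is the
    minimum run length for a call; ``max_gap`` (bp, ``None`` = unlimited)
    caps the genomic gap between consecutive member probes.
    """

    mode: str = "fixed"
    upper: float | None = None
    lower: float | None = None
    k: float = 3.0
    min_probes: int = 1
    max_gap: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "dynamic"):
            raise ValidationError(f"threshold mode must be fixed or dynamic, got {self.mode!r}")
        if self.mode == "fixed":
            if self.upper is None or self.lower is None:
                raise ValidationError("fixed mode requires explicit upper and lower thresholds")
            if not self.lower < self.upper:
                raise ValidationError("lower threshold must be below upper")
        if self.k <= 0:
            raise ValidationError("k must be positive")
        if self.min_probes < 1:
            raise ValidationError("min_probes must be >= 1")
        if self.max_gap is not None and self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")

    def resolve(self, values: np.ndarray) -> tuple[float, float]:
        """Return (lower, upper) for the given probe values."""
        if self.mode == "fixed":
            return float(self.lower), float(self.upper)  # type: ignore[arg-type]
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        if mad == 0.0:
            raise DegenerateNoiseError(
                "degenerate noise: MAD is 0, dynamic thresholds undefined; use fixed mode"
            )
        return med - self.k * mad, med + self.k * mad


@dataclass(frozen=True)
class NoiseEstimate:
    """Raw MAD of probe values around a reference (track median or segment means)."""

    mad: float
    reference: str

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValidationError("mad must be >= 0")
        if self.reference not in ("track_median", "segment_means"):
            raise ValidationError(f"unknown noise reference {self.reference!r}")


@dataclass(frozen=True)
class CbsParams:
    """Circular binary segmentation settings.

    ``alpha`` is the permutation significance level for accepting a split,
    ``n_perm`` the permutation count, ``min_width`` the minimum probes per
    segment, ``seed`` the mandatory RNG seed (the permutation test is
    stochastic; reproducibility requires pinning it).
    """

    alpha: float = 0.01
    n_perm: int = 10_000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValidationError("min_width must be >= 2")


HMM_STATES = ("loss", "neutral", "gain")


@dataclass(frozen=True)
class HmmParams:
    """3-state Gaussian-emission HMM for copy-number states.

    Defaults (means −0.5/0/+0.5, common SD 0.15, self-transition 0.99)
    reflect typical mosaicism-compressed aCGH single-copy levels; all are
    configurable.  Start distribution is uniform; off-diagonal transition
    mass ``1 − self_prob`` is split evenly between the two other states.
    """

    state_means: tuple[float, float, float] = (-0.5, 0.0, 0.5)
    state_sds: tuple[float, float, float] = (0.15, 0.15, 0.15)
    self_prob: float = 0.99

    def __post_init__(self) -> None:
        lo, mid, hi = self.state_means
        if not lo < mid < hi:
            raise ValidationError("state means must satisfy loss < neutral < gain")
        if any(s <= 0 for s in self.state_sds):
            raise ValidationError("state SDs must be positive")
        if not 0 < self.self_prob < 1:
            raise ValidationError("self_prob must be in (0, 1)")


# ---------------------------------------------------------------------------
# Noise


def estimate_noise(track: Track, segments: Sequence[Segment] | None = None) -> NoiseEstimate:
    """MAD of probe values around the track median, or around segment means.

    With ``segments`` given, every probe must fall in exactly one segment
    (matched by probe start position); deviations are then taken from the
    mean of the probe's segment — the residual spread after segmentation.
    """
    if len(track) == 0:
        raise ValidationError("cannot estimate noise on an empty track")
    values = track.values()
    if segments is None:
        med = float(np.median(values))
        mad = float(np.median(np.abs(values - med)))
        return NoiseEstimate(mad=mad, reference="track_median")

    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.interval.chrom, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.interval.start)
    deviations = np.empty(len(track))
    for i, m in enumerate(track.measurements):
        segs = by_chrom.get(m.interval.chrom, [])
        hits = [s for s in segs if s.interval.start <= m.interval.start < s.interval.end]
        if len(hits) != 1:
            raise ValidationError(
                f"probe at {m.interval} belongs to {len(hits)} segments; expected exactly 1"
            )
        deviations[i] = abs(m.value - hits[0].mean_value)
    return NoiseEstimate(mad=float(np.median(deviations)), reference="segment_means")


# ---------------------------------------------------------------------------
# Threshold calling


def _runs_to_calls(
    run: list[Measurement], direction: str, min_probes: int, sample: str
) -> list[CnvCall]:
    if len(run) < min_probes:
        return []
    iv = GenomicInterval(run[0].interval.chrom, run[0].interval.start, run[-1].interval.end)
    mean = float(np.mean([m.value for m in run]))
    seg = Segment(interval=iv, mean_value=mean, n_probes=len(run))
    return [CnvCall(segment=seg, direction=direction, sample=sample)]


def call_thresholds(
    track: Track, spec: ThresholdSpec, per_chrom_noise: bool = False
) -> list[CnvCall]:
    """Call gains/losses as maximal runs of probes beyond the thresholds.

    A run is a sequence of consecutive probes on one chromosome, all beyond
    the same threshold, with gaps between consecutive probes of at most
    ``spec.max_gap`` bp.  Runs shorter than ``spec.min_probes`` are dropped.
    ``per_chrom_noise`` resolves dynamic thresholds per chromosome instead
    of genome-wide.
    """
    if len(track) == 0:
        raise ValidationError("cannot call on an empty track")
    genome_thresholds = None if per_chrom_noise else spec.resolve(track.values())
    calls: list[CnvCall] = []
    for chrom, ms in track.by_chrom().items():
        lower, upper = (
            spec.resolve(np.array([m.value for m in ms]))
            if genome_thresholds is None
            else genome_thresholds
        )
        run: list[Measurement] = []
        run_dir: str | None = None
        for m in ms:
            d = "gain" if m.value > upper else ("loss" if m.value < lower else None)
            gap_ok = (
                not run
                or spec.max_gap is None
                or m.interval.start - run[-1].interval.end <= spec.max_gap
            )
            if d == run_dir and d is not None and gap_ok:
                run.append(m)
            else:
                if run_dir is not None:
                    calls.extend(_runs_to_calls(run, run_dir, spec.min_probes, track.name))
                run = [m] if d is not None else []
                run_dir = d
        if run_dir is not None:
            calls.extend(_runs_to_calls(run, run_dir, spec.min_probes, track.name))
    return calls


# ---------------------------------------------------------------------------
# Circular binary segmentation
#
# The change-point statistic for an arc (i, j] of the circularized probe
# sequence is the standardized difference between the arc mean and the mean
# of its complement:
#
#     Z(i, j) = |mean(x[i:j]) - mean(rest)| / sqrt(1/k + 1/(n-k)),  k = j - i.
#
# The common variance factor is omitted because the permutation test compares
# the observed maximum with maxima of permuted data, where any constant scale
# cancels.  Wrapping arcs need not be enumerated: a wrapping arc's statistic
# equals its contiguous complement's, and both imply the same two breakpoints.


def max_arc_statistic(
    values: np.ndarray, min_width: int = 2
) -> tuple[float, int, int] | None:
    """Maximize the arc statistic over all arcs (i, j] with both sides >= min_width.

    Returns ``(statistic, i, j)`` — the segment is ``values[i:j]`` — or
    ``None`` when no admissible arc exists.  Ties are broken by smallest
    ``i``, then smallest ``j``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * min_width:
        return None
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[n]
    best = -math.inf
    best_ij = (0, 0)
    for k in range(min_width, n - min_width + 1):
        sums = S[k:] - S[: n - k + 1]  # arc sums for i = 0 .. n-k
        denom = math.sqrt(1.0 / k + 1.0 / (n - k))
        stats = np.abs(sums / k - (total - sums) / (n - k)) / denom
        i = int(np.argmax(stats))  # first max → smallest i within this k
        s = float(stats[i])
        if s > best or (s == best and (i, i + k) < best_ij):
            best = s
            best_ij = (i, i + k)
    return best, best_ij[0], best_ij[1]


def _perm_max_stats(
    x: np.ndarray, n_perm: int, min_width: int, rng: np.random.Generator
) -> np.ndarray:
    """Maximum arc statistic of each of ``n_perm`` row-wise permutations of x."""
    n = len(x)
    perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
    S = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    total = S[:, n]
    best = np.full(n_perm, -np.inf)
    for k in range(min_width, n - min_width + 1):
        sums = S[:, k:] - S[:, : n - k + 1]
        denom = math.sqrt(1.0 / k + 1.0 / (n - k))
        stats = np.abs(sums / k - (total[:, None] - sums) / (n - k)) / denom
        np.maximum(best, stats.max(axis=1), out=best)
    return best


def _cbs_breakpoints(x: np.ndarray, params: CbsParams, rng: np.random.Generator) -> list[int]:
    """Sorted interior breakpoints of x found by recursive CBS."""
    n = len(x)
    found = max_arc_statistic(x, params.min_width)
    if found is None:
        return []
    stat, i, j = found
    if stat <= 0:  # constant data: no permutation can beat nothing
        return []
    perm_stats = _perm_max_stats(x, params.n_perm, params.min_width, rng)
    p = (1 + int(np.sum(perm_stats >= stat))) / (1 + params.n_perm)
    if p >= params.alpha:
        return []
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    out: list[int] = []
    for lo, hi in zip([0] + cuts, cuts + [n]):
        out.extend(b + lo for b in _cbs_breakpoints(x[lo:hi], params, rng))
        if hi < n:
            out.append(hi)
    return sorted(out)


def _segments_from_breaks(ms: list[Measurement], breaks: list[int]) -> list[Segment]:
    values = np.array([m.value for m in ms])
    bounds = [0] + breaks + [len(ms)]
    segs = []
    for lo, hi in zip(bounds, bounds[1:]):
        iv = GenomicInterval(ms[lo].interval.chrom, ms[lo].interval.start, ms[hi - 1].interval.end)
        segs.append(Segment(interval=iv, mean_value=float(values[lo:hi].mean()), n_probes=hi - lo))
    return segs


def cbs_segment(track: Track, params: CbsParams | None = None) -> list[Segment]:
    """Partition each chromosome's probes into segments by recursive CBS.

    The maximal arc statistic is computed exhaustively; its significance is
    assessed by ``n_perm`` permutations of the probe values, and splits with
    permutation p-value below ``alpha`` are accepted and recursed into.
    Chromosomes with fewer than 2 probes yield a single trivial segment.
    The output is an ordered, non-overlapping, exhaustive partition of the
    probes of every chromosome.
    """
    params = params or CbsParams()
    if len(track) == 0:
        raise ValidationError("cannot segment an empty track")
    rng = np.random.default_rng(params.seed)
    segments: list[Segment] = []
    for chrom, ms in track.by_chrom().items():
        if len(ms) < 2:
            segments.extend(_segments_from_breaks(ms, []))
            continue
        x = np.array([m.value for m in ms])
        breaks = _cbs_breakpoints(x, params, rng)
        segments.extend(_segments_from_breaks(ms, breaks))
    return segments


# ---------------------------------------------------------------------------
# Hidden Markov model


def viterbi_path(values: np.ndarray, params: HmmParams) -> np.ndarray:
    """Exact most-probable state path (0=loss, 1=neutral, 2=gain), log-space.

    Uniform start distribution; transition matrix has ``self_prob`` on the
    diagonal and ``(1 − self_prob)/2`` off it.  Ties in the backtrace resolve
    to the lowest state index, so decoding is deterministic.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    means = np.array(params.state_means)
    sds = np.array(params.state_sds)
    # Gaussian log density, constants kept so emissions are true log-probabilities
    log_emit = (
        -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds[None, :])
        - 0.5 * math.log(2 * math.pi)
    )
    log_trans = np.full((3, 3), math.log((1 - params.self_prob) / 2))
    np.fill_diagonal(log_trans, math.log(params.self_prob))
    log_start = math.log(1 / 3)

    delta = log_start + log_emit[0]
    back = np.zeros((n, 3), dtype=np.intp)
    for t in range(1, n):
        cand = delta[:, None] + log_trans  # cand[s_prev, s]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(3)] + log_emit[t]
    path = np.zeros(n, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def hmm_segment(track: Track, params: HmmParams | None = None) -> list[Segment]:
    """Segment each chromosome by exact Viterbi decoding of the 3-state HMM.

    Maximal same-state runs become segments; the decoded state label is kept
    on each segment so calling can map loss/gain directly.
    """
    params = params or HmmParams()
    if len(track) == 0:
        raise ValidationError("cannot segment an empty track")
    segments: list[Segment] = []
    for chrom, ms in track.by_chrom().items():
        x = np.array([m.value for m in ms])
        path = viterbi_path(x, params)
        lo = 0
        for hi in range(1, len(ms) + 1):
            if hi == len(ms) or path[hi] != path[lo]:
                iv = GenomicInterval(chrom, ms[lo].interval.start, ms[hi - 1].interval.end)
                segments.append(
                    Segment(
                        interval=iv,
                        mean_value=float(x[lo:hi].mean()),
                        n_probes=hi - lo,
                        state=HMM_STATES[path[lo]],
                    )
                )
                lo = hi
    return segments


# ---------------------------------------------------------------------------
# Quality score and segment-level calling


def quality_score(segment: Segment, noise: NoiseEstimate) -> float:
    """Segment mean divided by the MAD — a signed, robust signal-to-noise ratio."""
    if noise.mad <= 0:
        raise DegenerateNoiseError("degenerate noise: MAD is 0, quality score undefined")
    return segment.mean_value / noise.mad


def calls_from_segments(
    segments: Sequence[Segment],
    spec: ThresholdSpec,
    noise: NoiseEstimate,
    sample: str,
    track: Track | None = None,
) -> list[CnvCall]:
    """Turn segments beyond the thresholds into quality-scored calls.

    Segments whose mean exceeds ``upper`` become gains, those below ``lower``
    losses; neutral segments are dropped.  Dynamic thresholds need the probe
    values, so ``track`` is required in dynamic mode.
    """
    if spec.mode == "dynamic":
        if track is None:
            raise ValidationError("dynamic thresholds on segments require the source track")
        lower, upper = spec.resolve(track.values())
    else:
        lower, upper = spec.resolve(np.empty(0))
    calls: list[CnvCall] = []
    for seg in sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start)):
        if seg.mean_value > upper:
            direction = "gain"
        elif seg.mean_value < lower:
            direction = "loss"
        else:
            continue
        scored = Segment(
            interval=seg.interval,
            mean_value=seg.mean_value,
            n_probes=seg.n_probes,
            quality=quality_score(seg, noise),
            state=seg.state,
        )
        calls.append(CnvCall(segment=scored, direction=direction, sample=sample))
    return calls
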