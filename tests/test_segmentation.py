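"""Noise estimation, threshold calling, CBS, HMM and quality scoring."""

import itertools
import math

import numpy as np
import pytest

from cnvcat.core import (
    DegenerateNoiseError,
    GenomicInterval,
    Measurement,
    Segment,
    Track,
)
from cnvcat.segmentation import (
    CbsParams,
    HmmParams,
    NoiseEstimate,
    ThresholdSpec,
    call_thresholds,
    calls_from_segments,
    cbs_segment,
    estimate_noise,
    hmm_segment,
    max_arc_statistic,
    quality_score,
    viterbi_path,
)


def track_from_values(values, chrom="chr1", spacing=100, width=60, name="t"):
    ms = [
        Measurement(GenomicInterval(chrom, i * spacing, i * spacing + width), float(v))
        for i, v in enumerate(values)
    ]
    return Track.build(name, ms)


class TestEstimateNoise:
    def test_constant_track_has_zero_mad(self):
        assert estimate_noise(track_from_values([0, 0, 0, 0])).mad == 0.0

    def test_hand_computed_mad(self):
        # median 0, deviations [1, 0, 0, 1], median of those 0.5
        noise = estimate_noise(track_from_values([-1, 0, 0, 1]))
        assert noise.mad == 0.5
        assert noise.reference == "track_median"

    def test_segment_residual_mad_recovers_injected_noise(self, rng):
        """On a step track with perfect segments, the residual MAD equals the
        MAD of the injected noise alone, untouched by the step size."""
        noise_vals = rng.normal(0, 0.1, size=100)
        values = np.concatenate([noise_vals[:50], 2.0 + noise_vals[50:]])
        t = track_from_values(values)
        segs = [
            Segment(GenomicInterval("chr1", 0, 50 * 100), float(values[:50].mean()), 50),
            Segment(GenomicInterval("chr1", 50 * 100, 100 * 100), float(values[50:].mean()), 50),
        ]
        got = estimate_noise(t, segs).mad
        resid = np.concatenate([values[:50] - values[:50].mean(), values[50:] - values[50:].mean()])
        assert got == pytest.approx(np.median(np.abs(resid)), abs=1e-12)
        # close to the noise's own MAD (means estimated from 50 points)
        assert got == pytest.approx(np.median(np.abs(noise_vals - np.median(noise_vals))), rel=0.3)

    def test_probe_outside_all_segments_rejected(self):
        t = track_from_values([0.0, 1.0])
        segs = [Segment(GenomicInterval("chr1", 0, 60), 0.0, 1)]
        with pytest.raises(Exception, match="segments"):
            estimate_noise(t, segs)


class TestCallThresholds:
    def test_consecutive_gain_run(self):
        t = track_from_values([0.8, 0.9, 0.85])
        [call] = call_thresholds(t, ThresholdSpec(upper=0.3, lower=-0.3, min_probes=3))
        assert call.direction == "gain"
        assert call.segment.mean_value == pytest.approx(0.85)
        assert call.segment.n_probes == 3

    def test_all_within_thresholds_gives_no_calls(self):
        t = track_from_values([0.1, -0.2, 0.0, 0.25])
        assert call_thresholds(t, ThresholdSpec(upper=0.3, lower=-0.3)) == []

    def test_max_gap_splits_runs(self):
        ms = [
            Measurement(GenomicInterval("chr1", 0, 50), 1.0),
            Measurement(GenomicInterval("chr1", 100, 150), 1.0),
            Measurement(GenomicInterval("chr1", 5000, 5050), 1.0),
        ]
        t = Track.build("t", ms)
        calls = call_thresholds(t, ThresholdSpec(upper=0.3, lower=-0.3, max_gap=200))
        assert [c.segment.n_probes for c in calls] == [2, 1]

    def test_matches_run_length_scan_oracle(self, rng):
        """Randomized tracks: calls equal a brute-force run-length scan."""
        spec = ThresholdSpec(upper=0.5, lower=-0.5, min_probes=2)
        for _ in range(30):
            values = rng.normal(0, 0.6, size=40)
            t = track_from_values(values)
            got = [
                (c.direction, c.segment.n_probes, round(c.segment.mean_value, 10))
                for c in call_thresholds(t, spec)
            ]
            expected = []
            run = []
            run_dir = None
            for v in list(values) + [0.0]:  # sentinel flushes the last run
                d = "gain" if v > 0.5 else ("loss" if v < -0.5 else None)
                if d != run_dir:
                    if run_dir is not None and len(run) >= 2:
                        expected.append((run_dir, len(run), round(float(np.mean(run)), 10)))
                    run, run_dir = [], d
                if d is not None:
                    run.append(v)
            assert got == expected

    def test_dynamic_thresholds_shift_equivariant(self, rng):
        """Adding a constant shifts both thresholds, leaving the same probes called."""
        values = np.concatenate([rng.normal(0, 0.1, 30), rng.normal(1.5, 0.1, 10)])
        spec = ThresholdSpec(mode="dynamic", k=3, min_probes=2)
        base = call_thresholds(track_from_values(values), spec)
        shifted = call_thresholds(track_from_values(values + 0.4), spec)
        assert [(c.interval, c.direction) for c in base] == [
            (c.interval, c.direction) for c in shifted
        ]
        for a, b in zip(base, shifted):
            assert b.segment.mean_value == pytest.approx(a.segment.mean_value + 0.4)

    def test_dynamic_mode_with_zero_mad_is_degenerate(self):
        t = track_from_values([1.0] * 10)
        with pytest.raises(DegenerateNoiseError, match="fixed"):
            call_thresholds(t, ThresholdSpec(mode="dynamic"))


def brute_force_arc(x, min_width=2):
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    best, best_ij = -np.inf, None
    for i in range(n):
        for j in range(i + 1, n + 1):
            k = j - i
            if k < min_width or n - k < min_width:
                continue
            arc = S[j] - S[i]
            stat = abs(arc / k - (S[n] - arc) / (n - k)) / math.sqrt(1 / k + 1 / (n - k))
            if stat > best:
                best, best_ij = stat, (i, j)
    return best, best_ij


class TestCbs:
    def test_constant_track_yields_one_segment_per_chromosome(self):
        ms = [
            Measurement(GenomicInterval(c, i * 10, i * 10 + 5), 0.0)
            for c in ("chr1", "chr2")
            for i in range(100)
        ]
        segs = cbs_segment(Track.build("t", ms), CbsParams(n_perm=200, seed=1))
        assert len(segs) == 2
        assert {s.n_probes for s in segs} == {100}

    def test_single_probe_chromosome_gives_trivial_segment(self):
        t = track_from_values([0.7])
        [seg] = cbs_segment(t, CbsParams(n_perm=200, seed=1))
        assert seg.n_probes == 1 and seg.mean_value == 0.7

    def test_arc_statistic_matches_exhaustive_enumeration(self, rng):
        """For n <= 12 the vectorized max arc statistic equals brute force,
        including the (i, j) tie-break by smallest i then j."""
        for _ in range(60):
            n = int(rng.integers(4, 13))
            x = rng.normal(size=n)
            stat, i, j = max_arc_statistic(x, min_width=2)
            b_stat, b_ij = brute_force_arc(x)
            assert stat == pytest.approx(b_stat, abs=1e-12)
            assert (i, j) == b_ij

    def test_partition_invariants(self, rng):
        """Segments partition each chromosome's probes: sorted, abutting, counts sum."""
        values = np.concatenate([rng.normal(0, 0.1, 40), rng.normal(1, 0.1, 30), rng.normal(0, 0.1, 30)])
        t = track_from_values(values)
        segs = cbs_segment(t, CbsParams(n_perm=500, seed=2))
        assert sum(s.n_probes for s in segs) == 100
        for a, b in zip(segs, segs[1:]):
            assert a.interval.end <= b.interval.start

    def test_changepoint_recovery_on_seeded_replicates(self):
        """Single change at probe 50 (step 1.0, sd 0.05): localized within
        +/-2 probes in at least 9 of 10 seeded replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            values = np.concatenate([rng.normal(0, 0.05, 50), rng.normal(1, 0.05, 50)])
            segs = cbs_segment(track_from_values(values), CbsParams(n_perm=1000, seed=seed))
            boundaries = np.cumsum([s.n_probes for s in segs])[:-1]
            if len(boundaries) and min(abs(b - 50) for b in boundaries) <= 2:
                hits += 1
        assert hits >= 9


def brute_force_viterbi(x, params):
    """Exhaustive max-probability path over all 3^n state sequences."""
    log_trans = np.full((3, 3), math.log((1 - params.self_prob) / 2))
    np.fill_diagonal(log_trans, math.log(params.self_prob))
    means, sds = np.array(params.state_means), np.array(params.state_sds)

    def emit(t, s):
        return float(
            -0.5 * ((x[t] - means[s]) / sds[s]) ** 2 - math.log(sds[s]) - 0.5 * math.log(2 * math.pi)
        )

    best, best_path = -np.inf, None
    for path in itertools.product(range(3), repeat=len(x)):
        lp = math.log(1 / 3) + emit(0, path[0])
        for t in range(1, len(x)):
            lp += log_trans[path[t - 1], path[t]] + emit(t, path[t])
        if lp > best:
            best, best_path = lp, path
    return best, np.array(best_path)


def path_log_prob(x, path, params):
    log_trans = np.full((3, 3), math.log((1 - params.self_prob) / 2))
    np.fill_diagonal(log_trans, math.log(params.self_prob))
    means, sds = np.array(params.state_means), np.array(params.state_sds)
    lp = math.log(1 / 3)
    for t, s in enumerate(path):
        lp += float(
            -0.5 * ((x[t] - means[s]) / sds[s]) ** 2 - math.log(sds[s]) - 0.5 * math.log(2 * math.pi)
        )
        if t:
            lp += log_trans[path[t - 1], path[t]]
    return lp


class TestHmm:
    def test_constant_zero_track_is_all_neutral(self):
        t = track_from_values([0.0] * 30)
        [seg] = hmm_segment(t)
        assert seg.state == "neutral" and seg.n_probes == 30

    def test_step_track_decodes_neutral_then_gain(self, rng):
        values = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(0.5, 0.1, 20)])
        segs = hmm_segment(track_from_values(values), HmmParams(self_prob=0.99))
        assert [s.state for s in segs] == ["neutral", "gain"]
        assert [s.n_probes for s in segs] == [20, 20]

    def test_viterbi_matches_exhaustive_enumeration(self, rng):
        """Decoded path equals the argmax over all 3^10 paths on 10 probes."""
        params = HmmParams()
        for _ in range(10):
            x = rng.normal(0, 0.5, size=10)
            got = viterbi_path(x, params)
            _, expected = brute_force_viterbi(x, params)
            assert np.array_equal(got, expected)

    def test_decoded_path_beats_random_paths(self, rng):
        params = HmmParams()
        x = rng.normal(0, 0.4, size=25)
        decoded = viterbi_path(x, params)
        decoded_lp = path_log_prob(x, decoded, params)
        for _ in range(1000):
            rand = rng.integers(0, 3, size=25)
            assert decoded_lp >= path_log_prob(x, rand, params)


class TestQualityScore:
    def test_direct_formula(self):
        seg = Segment(GenomicInterval("chr1", 0, 100), mean_value=0.5, n_probes=5)
        assert quality_score(seg, NoiseEstimate(mad=0.1, reference="track_median")) == pytest.approx(5.0)

    def test_zero_mean_scores_zero(self):
        seg = Segment(GenomicInterval("chr1", 0, 100), mean_value=0.0, n_probes=5)
        assert quality_score(seg, NoiseEstimate(mad=0.7, reference="track_median")) == 0.0

    def test_zero_mad_is_degenerate(self):
        seg = Segment(GenomicInterval("chr1", 0, 100), mean_value=0.5, n_probes=5)
        with pytest.raises(DegenerateNoiseError):
            quality_score(seg, NoiseEstimate(mad=0.0, reference="track_median"))

    def test_homogeneous_of_degree_zero_under_scaling(self, rng):
        """Scaling all values by c scales mean and MAD alike; the score is unchanged."""
        values = rng.normal(0.3, 0.2, size=50)
        for c in (2.0, 7.5, 0.25):
            t1, tc = track_from_values(values), track_from_values(values * c)
            n1, nc = estimate_noise(t1), estimate_noise(tc)
            s1 = Segment(GenomicInterval("chr1", 0, 100), float(values.mean()), 50)
            sc = Segment(GenomicInterval("chr1", 0, 100), float(values.mean() * c), 50)
            assert quality_score(sc, nc) == pytest.approx(quality_score(s1, n1), rel=1e-9)


class TestCallsFromSegments:
    def make_segs(self, means):
        return [
            Segment(GenomicInterval("chr1", i * 1000, (i + 1) * 1000), m, 10)
            for i, m in enumerate(means)
        ]

    def test_gain_loss_and_neutral(self):
        noise = NoiseEstimate(mad=0.1, reference="track_median")
        calls = calls_from_segments(
            self.make_segs([0.02, 0.8, -0.6]), ThresholdSpec(upper=0.3, lower=-0.3), noise, "s1"
        )
        assert [(c.direction, c.segment.quality) for c in calls] == [
            ("gain", pytest.approx(8.0)),
            ("loss", pytest.approx(-6.0)),
        ]

    def test_all_neutral_gives_empty(self):
        noise = NoiseEstimate(mad=0.1, reference="track_median")
        assert (
            calls_from_segments(
                self.make_segs([0.1, -0.1]), ThresholdSpec(upper=0.3, lower=-0.3), noise, "s"
            )
            == []
        )

    def test_matches_elementwise_filter_oracle(self, rng):
        noise = NoiseEstimate(mad=0.2, reference="track_median")
        spec = ThresholdSpec(upper=0.4, lower=-0.4)
        for _ in range(20):
            means = rng.normal(0, 0.5, size=12)
            calls = calls_from_segments(self.make_segs(means), spec, noise, "s")
            expected = [
                ("gain" if m > 0.4 else "loss", i)
                for i, m in enumerate(means)
                if m > 0.4 or m < -0.4
            ]
            got = [(c.direction, c.segment.interval.start // 1000) for c in calls]
            assert got == expected
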