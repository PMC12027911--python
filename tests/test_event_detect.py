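"""Event caller: thresholds, oracle equivalence, and table round-trips."""

import numpy as np
import pandas as pd
import pytest

from nanosense.event_detect import (
    CurrentTrace,
    DetectionParams,
    TranslocationEvent,
    UnusableChannelError,
    detect_events,
    duration_tps_to_ms,
    estimate_open_current,
    events_to_frame,
    read_event_table,
    write_event_table,
)

IO = 220.0


def make_trace(samples, channel=1):
    return CurrentTrace(channel=channel, samples=np.asarray(samples, float))


def trace_with_dip(dip_len, dip_ratio, n=200, start=50, io=IO):
    samples = np.full(n, io)
    samples[start:start + dip_len] = dip_ratio * io
    return make_trace(samples)


def oracle_detect(samples, io, params=DetectionParams()):
    """Exhaustive scan over all below-threshold runs; the independent oracle."""
    events = []
    run = []
    for i, v in enumerate(list(samples) + [io]):  # sentinel closes a trailing run
        if v < params.all_ratio * io:
            run.append(i)
        elif run:
            seg = np.asarray([samples[j] for j in run])
            d = len(run)
            if params.min_duration_tps <= d <= params.max_duration_tps:
                mn = seg.min() / io
                if mn < params.lowest_ratio:
                    events.append((run[0], d, mn, seg.mean() / io))
            run = []
    return events


def as_tuples(events):
    return [(e.start_tp, e.duration_tps, pytest.approx(e.min_ir_io), pytest.approx(e.mean_ir_io))
            for e in events]


class TestOpenCurrent:
    def test_constant_trace(self):
        assert estimate_open_current(make_trace(np.full(1000, 220.0))) == 220.0

    def test_mode_ignores_minority_dips(self):
        samples = np.full(1000, 220.0)
        samples[::10] = 66.0  # 10% of samples inside deep blockades
        assert estimate_open_current(make_trace(samples)) == pytest.approx(220.0)

    def test_within_2pa_of_simulated_io(self):
        from nanosense.signal_sim import SimConfig, simulate_trace

        cfg = SimConfig(
            n_channels=1, run_minutes=0.2, open_current_mean=180.0, open_current_sd=0.0,
            probe_event_rate_per_100k_copies=500.0, background_event_rate=100.0,
            noisy_channel_fraction=0.0, pore_attrition_rate=0.0, seed=11,
        )
        traces, _ = simulate_trace(cfg, free_probe_copies=100_000)
        io = estimate_open_current(make_trace(traces[1]))
        assert abs(io - 180.0) <= 2.0

    def test_unusable_trace_raises(self):
        with pytest.raises(UnusableChannelError):
            estimate_open_current(make_trace(np.zeros(100)))


class TestDetectEvents:
    @pytest.mark.parametrize(
        "dip_len, dip_ratio, n_expected",
        [
            (10, 0.30, 1),  # a clean blockade
            (2, 0.30, 0),  # below the 4-tps duration floor
            (10, 0.57, 0),  # never dips under the 0.55 lowest-ratio bound
            (1200, 0.30, 1),  # at the duration ceiling
            (1201, 0.30, 0),  # just above the ceiling
        ],
    )
    def test_threshold_boundaries(self, dip_len, dip_ratio, n_expected):
        n = max(1500, dip_len + 100)
        events = detect_events(trace_with_dip(dip_len, dip_ratio, n=n), IO)
        assert len(events) == n_expected
        if n_expected:
            (e,) = events
            assert e.duration_tps == dip_len
            assert e.min_ir_io == pytest.approx(dip_ratio)

    def test_single_pulse_geometry(self):
        (e,) = detect_events(trace_with_dip(10, 0.30, start=50), IO)
        assert (e.start_tp, e.duration_tps) == (50, 10)
        assert e.mean_ir_io == pytest.approx(0.30)

    def test_oracle_equivalence_random_traces(self, rng):
        params = DetectionParams()
        for _ in range(300):
            n = int(rng.integers(50, 300))
            # currents hover around Io with frequent deep excursions so every
            # branch of the threshold logic is exercised
            samples = IO * rng.choice(
                [1.0, 0.8, 0.58, 0.5, 0.3, 0.1], size=n, p=[0.55, 0.1, 0.1, 0.1, 0.1, 0.05]
            )
            got = detect_events(make_trace(samples), IO, params)
            expected = oracle_detect(samples, IO, params)
            assert [(e.start_tp, e.duration_tps) for e in got] == [(s, d) for s, d, *_ in expected]
            for e, (_, _, mn, mean) in zip(got, expected):
                assert e.min_ir_io == pytest.approx(mn)
                assert e.mean_ir_io == pytest.approx(mean)

    def test_monotonicity_in_thresholds(self, rng):
        samples = IO * rng.choice([1.0, 0.56, 0.4, 0.2], size=2000, p=[0.6, 0.15, 0.15, 0.1])
        trace = make_trace(samples)
        base = len(detect_events(trace, IO, DetectionParams(lowest_ratio=0.45)))
        relaxed = len(detect_events(trace, IO, DetectionParams(lowest_ratio=0.55)))
        assert relaxed >= base
        wide = len(detect_events(trace, IO, DetectionParams()))
        narrow = len(detect_events(trace, IO, DetectionParams(min_duration_tps=8, max_duration_tps=600)))
        assert narrow <= wide

    def test_scale_invariance(self, rng):
        samples = IO * rng.choice([1.0, 0.5, 0.3], size=1000, p=[0.7, 0.2, 0.1])
        a = detect_events(make_trace(samples), IO)
        b = detect_events(make_trace(samples * 3.7), IO * 3.7)
        assert [(e.start_tp, e.duration_tps) for e in a] == [(e.start_tp, e.duration_tps) for e in b]
        np.testing.assert_allclose([e.min_ir_io for e in a], [e.min_ir_io for e in b])

    def test_events_sorted_and_nonoverlapping(self, rng):
        samples = IO * rng.choice([1.0, 0.3], size=3000, p=[0.8, 0.2])
        events = detect_events(make_trace(samples), IO)
        ends = -1
        for e in events:
            assert e.start_tp > ends
            ends = e.start_tp + e.duration_tps - 1


class TestDurationConversion:
    @pytest.mark.parametrize(
        "tps, rate, ms",
        [(1200, 3000.0, 400.0), (4, 3000.0, pytest.approx(4 / 3)), (0, 3000.0, 0.0)],
    )
    def test_examples(self, tps, rate, ms):
        assert duration_tps_to_ms(tps, rate) == ms

    def test_nonpositive_rate_raises(self):
        with pytest.raises(ValueError):
            duration_tps_to_ms(10, 0.0)


class TestEventTable:
    def test_empty_round_trip(self, tmp_path):
        path = tmp_path / "events.tsv"
        write_event_table([], path)
        assert path.read_text().splitlines() == ["channel\tstart_tp\tduration_tps\tmin_ir_io\tmean_ir_io"]
        assert read_event_table(path).empty

    def test_large_round_trip_lossless(self, tmp_path, rng):
        events = [
            TranslocationEvent(
                channel=int(rng.integers(1, 513)), start_tp=int(rng.integers(0, 10**6)),
                duration_tps=int(rng.integers(4, 1201)),
                min_ir_io=float(rng.uniform(0.05, 0.5)), mean_ir_io=float(rng.uniform(0.5, 0.6)),
            )
            for _ in range(1000)
        ]
        frame = events_to_frame(events)
        path = tmp_path / "events.tsv"
        write_event_table(frame, path)
        back = read_event_table(path)
        pd.testing.assert_frame_equal(back, frame)

    def test_stable_sort_order(self, tmp_path):
        events = [
            TranslocationEvent(channel=2, start_tp=5, duration_tps=4, min_ir_io=0.1, mean_ir_io=0.2),
            TranslocationEvent(channel=1, start_tp=9, duration_tps=4, min_ir_io=0.1, mean_ir_io=0.2),
            TranslocationEvent(channel=1, start_tp=2, duration_tps=4, min_ir_io=0.1, mean_ir_io=0.2),
        ]
        path = tmp_path / "events.tsv"
        write_event_table(events, path)
        back = read_event_table(path)
        assert list(zip(back.channel, back.start_tp)) == [(1, 2), (1, 9), (2, 5)]
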