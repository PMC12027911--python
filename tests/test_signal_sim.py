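"""Simulator: determinism, Poisson rates, recovery by the caller, attrition."""

import numpy as np
import pytest
from scipy import stats

from nanosense.event_detect import CurrentTrace, detect_events, estimate_open_current
from nanosense.signal_sim import (
    ConfigurationError,
    SimConfig,
    hybridize,
    simulate_trace,
    simulate_yenos_event_tables,
    simulate_yenos_experiment,
)

SMALL = dict(
    n_channels=4, run_minutes=0.2, noisy_channel_fraction=0.0, pore_attrition_rate=0.0
)


class TestHybridize:
    @pytest.mark.parametrize(
        "probe, target, eff, free",
        [
            (100_000, 0, 1.0, 100_000),
            (100_000, 100_000, 1.0, 0),  # exact stoichiometric silencing
            (150_000, 100_000, 1.0, 50_000),  # 1:1 binding arithmetic
            (100_000, 40_000, 0.5, 80_000),
            (50_000, 100_000, 1.0, 0),  # excess target floors at zero
        ],
    )
    def test_binding_arithmetic(self, probe, target, eff, free):
        assert hybridize(probe, target, eff) == free

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            hybridize(-1, 0)
        with pytest.raises(ValueError):
            hybridize(10, 10, efficiency=1.5)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_channels": 0},
            {"probe_blockade_mean": 0.4, "background_blockade_mean": 0.3},
            {"probe_blockade_mean": 1.2},
            {"background_event_rate": -1},
            {"pore_attrition_rate": 1.5},
            {"run_minutes": 0},
        ],
    )
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestTraceSimulation:
    def test_quiet_flowcell_yields_no_events(self):
        cfg = SimConfig(**SMALL, background_event_rate=0.0, seed=1)
        traces, truth = simulate_trace(cfg, free_probe_copies=0)
        assert truth.events.empty
        for ch, sig in traces.items():
            trace = CurrentTrace(channel=ch, samples=sig)
            assert detect_events(trace, estimate_open_current(trace)) == []

    def test_seed_determinism_sample_for_sample(self):
        cfg = SimConfig(**SMALL, seed=7, background_event_rate=100.0)
        t1, g1 = simulate_trace(cfg, free_probe_copies=50_000)
        t2, g2 = simulate_trace(cfg, free_probe_copies=50_000)
        assert t1.keys() == t2.keys()
        for ch in t1:
            np.testing.assert_array_equal(t1[ch], t2[ch])
        assert g1.events.equals(g2.events)

    def test_injected_probe_counts_match_poisson_rate(self):
        # per-channel injected probe-event counts across seeded replicates
        # follow the configured Poisson law (chi-square GOF, alpha = 0.01)
        lam = 5.0
        counts = []
        for seed in range(100):
            # quiet traces keep dip collisions (and thus thinning of the
            # injected list) negligible, so counts stay Poisson
            cfg = SimConfig(
                n_channels=8, run_minutes=0.45, noisy_channel_fraction=0.0,
                pore_attrition_rate=0.0, background_event_rate=0.0,
                probe_event_rate_per_100k_copies=lam / 0.01, seed=seed,
            )
            _, truth = simulate_trace(cfg, free_probe_copies=100_000)
            per_channel = truth.events.groupby("channel").size()
            counts.extend(per_channel.reindex(range(1, 9), fill_value=0))
        counts = np.asarray(counts)
        assert counts.size == 800
        kmax = int(counts.max())
        observed = np.bincount(counts, minlength=kmax + 1).astype(float)
        expected = stats.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
        expected[-1] += stats.poisson.sf(kmax, lam) * counts.size
        # merge sparse tails so every expected cell is >= 5
        while expected[0] < 5:
            expected[1] += expected[0]; observed[1] += observed[0]
            expected, observed = expected[1:], observed[1:]
        while expected[-1] < 5:
            expected[-2] += expected[-1]; observed[-2] += observed[-1]
            expected, observed = expected[:-1], observed[:-1]
        chi2 = ((observed - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=len(expected) - 1)
        assert p > 0.01

    def test_caller_recovers_injected_events(self):
        # >= 95% of injected events with duration in [4,1200] and depth < 0.55
        # are recovered; sub-4-tps fast-RNA dips are never recovered
        cfg = SimConfig(
            n_channels=6, run_minutes=0.5, seed=3, noisy_channel_fraction=0.0,
            pore_attrition_rate=0.0, background_event_rate=2000.0,
            probe_event_rate_per_100k_copies=2000.0,
        )
        traces, truth = simulate_trace(
            cfg, free_probe_copies=100_000, unhybridized_rna_copies=50_000
        )
        assert (truth.events.population == "fast_rna").any()
        eligible = matched = fast_recovered = 0
        for ch, sig in traces.items():
            trace = CurrentTrace(channel=ch, samples=sig)
            called = detect_events(trace, estimate_open_current(trace))
            intervals = [(e.start_tp, e.start_tp + e.duration_tps) for e in called]
            sub = truth.events[truth.events.channel == ch]
            for row in sub.itertuples():
                hit = any(s < row.start_tp + row.duration_tps and e > row.start_tp
                          for s, e in intervals)
                if row.population == "fast_rna":
                    fast_recovered += hit
                elif row.ir_io < 0.55 and 4 <= row.duration_tps <= 1200:
                    eligible += 1
                    matched += hit
        assert eligible > 100
        assert matched / eligible >= 0.95
        assert fast_recovered == 0


class TestYenosExperiment:
    def test_buffer_runs_are_probe_free(self):
        cfg = SimConfig(**SMALL, seed=2, background_event_rate=50.0)
        runs = simulate_yenos_experiment(cfg, probe_copies=100_000, target_copies=0)
        assert runs.run_kinds == ["buffer", "buffer", "sample", "sample"]
        for kind, truth in zip(runs.run_kinds, runs.truths):
            if kind == "buffer":
                assert truth.free_probe_copies == 0
                assert not (truth.events.population == "probe").any()
            else:
                assert truth.free_probe_copies == 100_000

    def test_attrition_shrinks_active_channels_monotonically(self):
        cfg = SimConfig(
            n_channels=60, run_minutes=0.05, pore_attrition_rate=0.3,
            noisy_channel_fraction=0.0, background_event_rate=5.0, seed=4,
        )
        runs = simulate_yenos_experiment(cfg, probe_copies=0, target_copies=0)
        active = [len(t.active_channels) for t in runs.truths]
        assert all(a >= b for a, b in zip(active, active[1:]))
        assert active[-1] < active[0]  # 1 - 0.7^4 of channels lost in expectation

    def test_event_tables_deterministic_and_buffer_probe_free(self):
        cfg = SimConfig(seed=12, n_channels=64, run_minutes=2.0)
        a = simulate_yenos_event_tables(cfg, 104_160, 0)
        b = simulate_yenos_event_tables(cfg, 104_160, 0)
        for (ka, ta), (kb, tb) in zip(a, b):
            assert ka == kb
            assert ta.equals(tb)
        # identical substreams for the two buffer runs' populations differ only
        # through the run index, so the tables must not be accidentally shared
        assert not a[0][1].equals(a[1][1])

    def test_noisy_channel_fraction_materialises(self):
        from nanosense.decision import qc_filter_channels

        cfg = SimConfig(seed=9, n_channels=400, noisy_channel_fraction=0.05)
        (_, table), *_ = simulate_yenos_event_tables(cfg, 0, 0)
        _, removed = qc_filter_channels(table, 20_000)
        assert 0.01 <= len(removed) / 400 <= 0.10  # ~5% of channels
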