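"""Synthetic nanopore-array experiments with known ground truth.

The sensing assay mixes an osmium-tagged probe (complementary to one target
miRNA) with a total-RNA isolate.  Free probe molecules translocate slowly
and produce deep blockades (Ir/Io near 0.15); probe hybridized to its
target forms a duplex too wide for the pore and is silenced.  Device noise
and untagged RNA produce a background of events, a mixture of an early
noise mode (~0.15) and a late, shallower mode (~0.30); most untagged RNA
translocations are too fast for the acquisition rate and never register.

The simulator renders either full per-channel current traces (square dips
on a constant-plus-noise open-pore level) or, on a fast path, the per-event
tables the caller would produce, from the same generative model:

* per-channel event counts are Poisson with rates linear in copy numbers
  (a single calibration constant maps free-probe copies to events);
* blockade depths are Gaussian within each population;
* a configurable fraction of channels is "noisy" (> 20,000 events/run,
  removed downstream by QC) and pores attrit run over run;
* every random draw descends deterministically from (seed, run, channel).

A four-run experiment — two buffer runs then two sample runs — is the
decision unit consumed by :mod:`nanosense.decision`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .event_detect import EVENT_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "YenosRuns",
    "ConfigurationError",
    "hybridize",
    "simulate_trace",
    "simulate_yenos_experiment",
    "simulate_yenos_event_tables",
    "write_run_h5",
    "read_run_h5",
    "write_ground_truth",
    "read_ground_truth",
]

REFERENCE_RUN_MINUTES = 45.0  # event rates are quoted per 45-min run

TRUTH_COLUMNS = ["channel", "start_tp", "duration_tps", "population", "ir_io"]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulator settings; defaults emulate the optimized 45-min protocol.

    Rates are events per channel per 45-min run.  The copies-to-event-rate
    mapping is linear: ``probe_event_rate_per_100k_copies`` events per
    channel per run for every 100,000 free-probe copies in the mixture (the
    assay's working point keeps probe copies near 100,000).
    """

    n_channels: int = 512
    run_minutes: float = 45.0
    sampling_rate: float = 3000.0
    open_current_mean: float = 220.0
    open_current_sd: float = 2.0
    trace_noise_pa: float = 1.5
    probe_blockade_mean: float = 0.15
    probe_blockade_sd: float = 0.03
    background_blockade_mean: float = 0.30
    background_blockade_sd: float = 0.05
    background_early_fraction: float = 0.25
    probe_event_rate_per_100k_copies: float = 60.0
    background_event_rate: float = 60.0
    fast_rna_miss_fraction: float = 0.95
    pore_attrition_rate: float = 0.05
    noisy_channel_fraction: float = 0.02
    noisy_channel_events: int = 22000
    within_event_noise_pa: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.run_minutes <= 0 or self.sampling_rate <= 0:
            raise ConfigurationError("run_minutes and sampling_rate must be positive")
        for name in ("probe_blockade_mean", "background_blockade_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0,1)")
        if self.probe_blockade_mean >= self.background_blockade_mean:
            raise ConfigurationError("probe blockade mean must be below background mean")
        for name in ("probe_event_rate_per_100k_copies", "background_event_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("pore_attrition_rate", "noisy_channel_fraction",
                     "fast_rna_miss_fraction", "background_early_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0,1]")
        if self.open_current_mean <= 0:
            raise ConfigurationError("open_current_mean must be positive")

    @property
    def samples_per_run(self) -> int:
        return int(round(self.run_minutes * 60.0 * self.sampling_rate))

    @property
    def run_scale(self) -> float:
        """Fraction of the reference 45-min run this configuration covers."""
        return self.run_minutes / REFERENCE_RUN_MINUTES


@dataclass
class GroundTruth:
    """Everything the simulator injected, for oracle-style checks."""

    probe_copies: int
    target_copies: int
    free_probe_copies: int
    events: pd.DataFrame  # columns: channel, start_tp, duration_tps, population, ir_io
    active_channels: list[int] = field(default_factory=list)
    noisy_channels: list[int] = field(default_factory=list)


@dataclass
class YenosRuns:
    """One four-run experiment: two buffer runs, then two sample runs."""

    run_kinds: list[str]
    traces: list[dict[int, np.ndarray]]
    truths: list[GroundTruth]
    config: SimConfig


def hybridize(probe_copies: int, target_copies: int, efficiency: float = 1.0) -> int:
    """Free probe copies after 1:1 hybridization with the target."""
    if probe_copies < 0 or target_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0,1]")
    hybridized = efficiency * min(probe_copies, target_copies)
    return max(0, int(round(probe_copies - hybridized)))


# ---------------------------------------------------------------------------
# deterministic substreams
# ---------------------------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(k) for k in key)))


def _channel_alive(config: SimConfig, channel: int, run_index: int) -> bool:
    """Pore attrition: channel death times are fixed per seed; a channel dead
    in run r stays dead in every later run."""
    if config.pore_attrition_rate == 0.0:
        return True
    u = _rng(config.seed, 900, channel).uniform()
    survive = (1.0 - config.pore_attrition_rate) ** (run_index + 1)
    return u < survive


def _channel_noisy(config: SimConfig, channel: int, run_index: int) -> bool:
    if config.noisy_channel_fraction == 0.0:
        return False
    u = _rng(config.seed, 901, channel, run_index).uniform()
    return u < config.noisy_channel_fraction


# ---------------------------------------------------------------------------
# event drawing (shared by trace rendering and the event-table fast path)
# ---------------------------------------------------------------------------

def _draw_channel_events(
    rng: np.random.Generator,
    config: SimConfig,
    free_probe_copies: float,
    unhybridized_rna_copies: float,
    noisy: bool,
) -> pd.DataFrame:
    """Draw injected events for one channel of one run.

    Populations: 'probe' (deep, slow), 'background' (device noise mixture of
    an early and a late mode), 'rna' (registered slow tail of target-RNA
    translocations), 'fast_rna' (sub-4-tps dips that can never be called).
    """
    scale = config.run_scale
    n_probe = rng.poisson(config.probe_event_rate_per_100k_copies * free_probe_copies / 1e5 * scale)
    if noisy:
        n_back = config.noisy_channel_events + rng.poisson(1000.0 * scale)
    else:
        n_back = rng.poisson(config.background_event_rate * scale)
    rna_attempt_rate = config.probe_event_rate_per_100k_copies * unhybridized_rna_copies / 1e5 * scale
    n_rna_attempts = rng.poisson(rna_attempt_rate)
    n_fast = rng.binomial(n_rna_attempts, config.fast_rna_miss_fraction) if n_rna_attempts else 0
    n_rna = n_rna_attempts - n_fast

    pops: list[np.ndarray] = []
    ratios: list[np.ndarray] = []
    durations: list[np.ndarray] = []

    if n_probe:
        pops.append(np.repeat("probe", n_probe))
        ratios.append(rng.normal(config.probe_blockade_mean, config.probe_blockade_sd, n_probe))
        durations.append(_lognormal_durations(rng, n_probe, median=60.0, sigma=0.8))
    if n_back:
        early = rng.random(n_back) < config.background_early_fraction
        r = np.where(
            early,
            rng.normal(config.probe_blockade_mean, config.probe_blockade_sd, n_back),
            rng.normal(config.background_blockade_mean, config.background_blockade_sd, n_back),
        )
        pops.append(np.repeat("background", n_back))
        ratios.append(r)
        durations.append(_lognormal_durations(rng, n_back, median=12.0, sigma=0.7))
    if n_rna:
        pops.append(np.repeat("rna", n_rna))
        ratios.append(rng.normal(config.background_blockade_mean, config.background_blockade_sd, n_rna))
        durations.append(_lognormal_durations(rng, n_rna, median=6.0, sigma=0.5))
    if n_fast:
        pops.append(np.repeat("fast_rna", n_fast))
        ratios.append(rng.normal(config.background_blockade_mean, config.background_blockade_sd, n_fast))
        durations.append(rng.integers(1, 4, n_fast))

    if not pops:
        return pd.DataFrame(columns=TRUTH_COLUMNS[1:])

    ratio = np.clip(np.concatenate(ratios), 0.02, 0.98)
    duration = np.concatenate(durations).astype(np.int64)
    population = np.concatenate(pops)
    n_samples = config.samples_per_run
    start = rng.integers(0, np.maximum(1, n_samples - duration))
    frame = pd.DataFrame(
        {"start_tp": start, "duration_tps": duration, "population": population, "ir_io": ratio}
    ).sort_values("start_tp", kind="mergesort").reset_index(drop=True)
    return frame


def _lognormal_durations(rng, n, median, sigma, lo=4, hi=1200):
    d = np.exp(rng.normal(np.log(median), sigma, n))
    return np.clip(np.round(d), lo, hi).astype(np.int64)


def _drop_overlaps(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep earlier events when injected dips would collide (needs a >=1
    sample open-pore gap so adjacent events cannot merge into one run)."""
    if frame.empty:
        return frame
    keep = []
    next_free = -1
    for row in frame.itertuples(index=False):
        if row.start_tp > next_free:
            keep.append(True)
            next_free = row.start_tp + row.duration_tps
        else:
            keep.append(False)
    return frame[np.array(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trace rendering
# ---------------------------------------------------------------------------

def simulate_trace(
    config: SimConfig,
    free_probe_copies: int,
    *,
    probe_copies: int | None = None,
    target_copies: int = 0,
    unhybridized_rna_copies: float = 0.0,
    run_index: int = 0,
) -> tuple[dict[int, np.ndarray], GroundTruth]:
    """Render per-channel current traces with injected blockade dips.

    Returns a mapping channel -> float32 pA array, plus the ground truth of
    every injected (and kept) event.  Channels lost to attrition by
    ``run_index`` emit no trace.  Identical (config, arguments) are
    bit-identical run to run.
    """
    if free_probe_copies < 0:
        raise ValueError("free_probe_copies must be >= 0")
    n_samples = config.samples_per_run
    traces: dict[int, np.ndarray] = {}
    truth_frames = []
    active, noisy_list = [], []
    for channel in range(1, config.n_channels + 1):
        if not _channel_alive(config, channel, run_index):
            continue
        active.append(channel)
        noisy = _channel_noisy(config, channel, run_index)
        if noisy:
            noisy_list.append(channel)
        rng = _rng(config.seed, run_index, channel)
        io = rng.normal(config.open_current_mean, config.open_current_sd)
        io = max(io, 1.0)
        signal = rng.normal(io, config.trace_noise_pa, n_samples).astype(np.float32)
        events = _drop_overlaps(
            _draw_channel_events(rng, config, free_probe_copies, unhybridized_rna_copies, noisy)
        )
        for row in events.itertuples(index=False):
            s, d = int(row.start_tp), int(row.duration_tps)
            d = min(d, n_samples - s)  # dips cannot outlast the run
            if d <= 0:
                continue
            level = row.ir_io * io
            signal[s:s + d] = rng.normal(level, config.within_event_noise_pa, d).astype(np.float32)
        traces[channel] = signal
        if not events.empty:
            events = events.copy()
            events.insert(0, "channel", channel)
            truth_frames.append(events)
    truth_events = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(columns=TRUTH_COLUMNS)
    )
    probe_copies = free_probe_copies if probe_copies is None else probe_copies
    truth = GroundTruth(
        probe_copies=int(probe_copies),
        target_copies=int(target_copies),
        free_probe_copies=int(free_probe_copies),
        events=truth_events,
        active_channels=active,
        noisy_channels=noisy_list,
    )
    return traces, truth


def simulate_yenos_experiment(
    config: SimConfig,
    probe_copies: int,
    target_copies: int,
    efficiency: float = 1.0,
) -> YenosRuns:
    """Simulate one full test: two buffer runs followed by two sample runs.

    Buffer runs contain background events only; sample runs add probe
    events in proportion to the free (unhybridized) probe.  Attrition
    reduces the active channels run over run.
    """
    free = hybridize(probe_copies, target_copies, efficiency)
    unhybridized_rna = max(0, target_copies - min(probe_copies, target_copies))
    kinds = ["buffer", "buffer", "sample", "sample"]
    traces, truths = [], []
    for run_index, kind in enumerate(kinds):
        if kind == "buffer":
            t, g = simulate_trace(config, 0, probe_copies=0, target_copies=0, run_index=run_index)
        else:
            t, g = simulate_trace(
                config, free, probe_copies=probe_copies, target_copies=target_copies,
                unhybridized_rna_copies=unhybridized_rna, run_index=run_index,
            )
        traces.append(t)
        truths.append(g)
    return YenosRuns(run_kinds=kinds, traces=traces, truths=truths, config=config)


# ---------------------------------------------------------------------------
# event-table fast path
# ---------------------------------------------------------------------------

def _event_table_for_run(config: SimConfig, free_probe: float, unhyb_rna: float, run_index: int) -> pd.DataFrame:
    """Vectorised per-run event table (callable events only).

    Statistically identical to rendering traces and calling events, but all
    channels of a run are drawn from one substream so that 512-channel runs
    cost milliseconds.
    """
    n = config.n_channels
    scale = config.run_scale
    u_death = _rng(config.seed, 902).uniform(size=n)
    alive = u_death < (1.0 - config.pore_attrition_rate) ** (run_index + 1)
    rng = _rng(config.seed, 800, run_index)
    noisy = (rng.uniform(size=n) < config.noisy_channel_fraction) & alive

    n_probe = np.where(
        alive, rng.poisson(config.probe_event_rate_per_100k_copies * free_probe / 1e5 * scale, n), 0
    )
    n_back = np.where(alive, rng.poisson(config.background_event_rate * scale, n), 0)
    n_back = np.where(noisy, config.noisy_channel_events + rng.poisson(1000.0 * scale, n), n_back)
    # fast-RNA misses never register: thinned Poisson for the slow tail only
    rna_rate = (
        config.probe_event_rate_per_100k_copies * unhyb_rna / 1e5
        * (1.0 - config.fast_rna_miss_fraction) * scale
    )
    n_rna = np.where(alive, rng.poisson(rna_rate, n), 0) if rna_rate > 0 else np.zeros(n, np.int64)

    channels = np.arange(1, n + 1)
    ch_col, ratio_col, dur_col = [], [], []
    total_probe = int(n_probe.sum())
    if total_probe:
        ch_col.append(np.repeat(channels, n_probe))
        ratio_col.append(rng.normal(config.probe_blockade_mean, config.probe_blockade_sd, total_probe))
        dur_col.append(_lognormal_durations(rng, total_probe, median=60.0, sigma=0.8))
    total_back = int(n_back.sum())
    if total_back:
        early = rng.random(total_back) < config.background_early_fraction
        r = np.where(
            early,
            rng.normal(config.probe_blockade_mean, config.probe_blockade_sd, total_back),
            rng.normal(config.background_blockade_mean, config.background_blockade_sd, total_back),
        )
        ch_col.append(np.repeat(channels, n_back))
        ratio_col.append(r)
        dur_col.append(_lognormal_durations(rng, total_back, median=12.0, sigma=0.7))
    total_rna = int(n_rna.sum())
    if total_rna:
        ch_col.append(np.repeat(channels, n_rna))
        ratio_col.append(rng.normal(config.background_blockade_mean, config.background_blockade_sd, total_rna))
        dur_col.append(_lognormal_durations(rng, total_rna, median=6.0, sigma=0.5))

    if not ch_col:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    channel = np.concatenate(ch_col)
    ratio = np.clip(np.concatenate(ratio_col), 0.02, 0.98)
    duration = np.concatenate(dur_col)
    start = rng.integers(0, max(1, config.samples_per_run - 1200), channel.size)
    # left unsorted: the decision statistic is order-free, and sorting would
    # dominate the cost of replicated runs (write_event_table sorts on write)
    return pd.DataFrame(
        {
            "channel": channel,
            "start_tp": start,
            "duration_tps": duration,
            "min_ir_io": ratio,
            "mean_ir_io": ratio,
        }
    )


def simulate_yenos_event_tables(
    config: SimConfig,
    probe_copies: int,
    target_copies: int,
    efficiency: float = 1.0,
) -> list[tuple[str, pd.DataFrame]]:
    """Fast path: per-run called-event tables without waveform rendering.

    Uses the same generative model as :func:`simulate_trace` (same rates,
    populations, attrition, noisy channels) but emits the event table the
    caller would produce, with the nominal blockade depth standing in for
    the rendered minimum.  Suitable for replicated statistical checks where
    rendering 45-min, 512-channel waveforms is prohibitive.
    """
    free = hybridize(probe_copies, target_copies, efficiency)
    unhyb = max(0, target_copies - min(probe_copies, target_copies))
    out = []
    for run_index, kind in enumerate(["buffer", "buffer", "sample", "sample"]):
        if kind == "buffer":
            table = _event_table_for_run(config, 0.0, 0.0, run_index)
        else:
            table = _event_table_for_run(config, free, unhyb, run_index)
        out.append((kind, table))
    return out


# ---------------------------------------------------------------------------
# trace container (HDF5) and ground-truth sidecar (TSV)
# ---------------------------------------------------------------------------

def write_run_h5(
    path: str | Path,
    traces: dict[int, np.ndarray],
    *,
    sampling_rate: float,
    run_minutes: float,
    run_kind: str,
    bias_mv: float = -180.0,
) -> None:
    """One run per HDF5 file: /meta attributes + /channels/<id>/signal."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["sampling_rate_hz"] = float(sampling_rate)
        meta.attrs["run_minutes"] = float(run_minutes)
        meta.attrs["bias_mv"] = float(bias_mv)
        meta.attrs["run_kind"] = run_kind
        channels = f.create_group("channels")
        for channel, signal in sorted(traces.items()):
            g = channels.create_group(str(channel))
            g.create_dataset("signal", data=np.asarray(signal, dtype=np.float32))


def read_run_h5(path: str | Path) -> tuple[dict[int, np.ndarray], dict]:
    with h5py.File(path, "r") as f:
        meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in f["meta"].attrs.items()}
        traces = {int(cid): f["channels"][cid]["signal"][...] for cid in f["channels"]}
    return traces, meta


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    truth.events[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
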