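"""Detection/silencing decision from buffer and sample event tables.

Called events are histogrammed by their deepest blockade (min Ir/Io) in
0.05-wide bins.  Histograms show two maxima: an early one near 0.15 where
osmium-tagged probes translocate and a late one near 0.30 produced by
device noise and untagged RNA.  The decision statistic is

    R = (events in the late modal bin) / (events in the early modal bin).

Adding free probe feeds the early maximum, so R *drops* relative to the
probe-free buffer: a relative decrease of more than 18% is called
*detection*; a comparable or increasing R is *silencing* (probe fully
hybridized).  One test pools two buffer runs and requires two concordant
sample runs; quality rules reject tests with too few active pores, a
blockade-maximum shift beyond +/-0.05, a gross event excess, or
disagreeing sample runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "BlockadeHistogram",
    "RunResult",
    "YenosTestResult",
    "DecisionParams",
    "UndefinedRatioError",
    "qc_filter_channels",
    "build_histogram",
    "ratio_R",
    "classify",
    "run_result_from_events",
    "run_yenos_test",
]

BIN_WIDTH = 0.05
BIN_EDGES = np.round(np.arange(0.05, 0.60 + BIN_WIDTH / 2, BIN_WIDTH), 10)  # [0.05, 0.60)
BIN_LABELS = BIN_EDGES[:-1]  # left edge labels the bin, matching the 0.15/0.30 maxima
EARLY_WINDOW = (0.10, 0.20)  # label range for the early (probe) maximum
LATE_WINDOW = (0.25, 0.35)  # label range for the late (background) maximum
EARLY_NOMINAL = 0.15
LATE_NOMINAL = 0.30


class UndefinedRatioError(ValueError):
    """The early maximum holds no events; R (and the test) is unusable."""


@dataclass(frozen=True)
class DecisionParams:
    """Decision thresholds; defaults are the optimized-protocol values."""

    significance: float = 0.18  # relative change in R deemed significant
    channel_event_cap: int = 20000  # QC: drop channels reporting more events
    min_active_channels: int = 200  # reject unless strictly more pores are active
    excess_factor: float = 3.0  # sample/buffer total-event ratio treated as gross excess
    max_shift: float = 0.05  # allowed drift of either blockade maximum
    count_mode: Literal["modal", "window_sum"] = "modal"

    def __post_init__(self):
        if self.significance <= 0:
            raise ValueError("significance must be positive")
        if self.excess_factor <= 0:
            raise ValueError("excess_factor must be positive")


@dataclass
class BlockadeHistogram:
    """Event counts in 0.05-wide blockade bins over [0.05, 0.60).

    ``early_count``/``late_count`` are the counts of the modal bin inside
    each nominal window (or window sums, per ``count_mode``);
    ``early_peak``/``late_peak`` are where the two dominant maxima of the
    whole histogram actually sit, used for the drift check.
    """

    counts: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: BIN_EDGES.copy())
    early_max_bin: float | None = None
    late_max_bin: float | None = None
    early_count: int = 0
    late_count: int = 0
    early_peak: float | None = None
    late_peak: float | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def defined(self) -> bool:
        return self.early_count > 0 and self.late_count > 0


@dataclass
class RunResult:
    """Summary of one 45-min run after channel QC."""

    run_kind: str
    histogram: BlockadeHistogram
    R: float | None
    active_channels: int
    total_events: int
    removed_channels: list[int]


@dataclass
class YenosTestResult:
    """Outcome of one four-run test (two buffer + two sample runs)."""

    buffer_runs: list[RunResult]
    sample_runs: list[RunResult]
    pooled_buffer_R: float | None
    relative_R_change: list[float]
    call: Literal["detection", "silencing", "rejected"]
    rejection_reason: Literal["none", "disagreement", "max_shift", "event_excess",
                              "too_few_pores", "undefined_R"] = "none"

    def to_dict(self) -> dict:
        return {
            "call": self.call,
            "rejection_reason": self.rejection_reason,
            "pooled_buffer_R": self.pooled_buffer_R,
            "relative_R_change": self.relative_R_change,
            "buffer": [_run_dict(r) for r in self.buffer_runs],
            "sample": [_run_dict(r) for r in self.sample_runs],
        }


def _run_dict(r: RunResult) -> dict:
    return {
        "run_kind": r.run_kind,
        "R": r.R,
        "active_channels": r.active_channels,
        "total_events": r.total_events,
        "removed_channels": list(r.removed_channels),
        "counts": r.histogram.counts.tolist(),
    }


def qc_filter_channels(
    events: pd.DataFrame, channel_event_cap: int = 20000
) -> tuple[pd.DataFrame, list[int]]:
    """Drop channels reporting more than ``channel_event_cap`` events.

    Channels at exactly the cap are kept.  Returns the filtered table and
    the sorted list of removed channels.
    """
    if events.empty:
        return events, []
    per_channel = events["channel"].value_counts()
    removed = sorted(int(c) for c in per_channel[per_channel > channel_event_cap].index)
    if not removed:
        return events, []
    return events[~events["channel"].isin(removed)].reset_index(drop=True), removed


def _window_slice(window: tuple[float, float]) -> np.ndarray:
    return np.flatnonzero((BIN_LABELS >= window[0] - 1e-9) & (BIN_LABELS < window[1] - 1e-9))


def _locate_peaks(counts: np.ndarray) -> tuple[float | None, float | None]:
    """Positions (bin labels) of the two dominant local maxima.

    Plateaus count once; if only one local maximum exists it is assigned to
    whichever nominal position it is closer to.
    """
    padded = np.concatenate(([-1.0], counts.astype(float), [-1.0]))
    idx, props = find_peaks(padded, plateau_size=1)
    if idx.size == 0:
        return None, None
    labels = BIN_LABELS[idx - 1]
    heights = padded[idx]
    order = np.argsort(heights)[::-1]
    top = sorted(labels[order[:2]])
    if len(top) == 1 or idx.size == 1:
        pos = top[0]
        if abs(pos - EARLY_NOMINAL) <= abs(pos - LATE_NOMINAL):
            return pos, None
        return None, pos
    return top[0], top[1]


def build_histogram(
    events: pd.DataFrame | Iterable[float],
    count_mode: Literal["modal", "window_sum"] = "modal",
) -> BlockadeHistogram:
    """Histogram per-event min Ir/Io in 0.05 bins and locate both maxima.

    Ties between bins break toward the lower bin.  With zero events the
    maxima are left undefined and the histogram is flagged unusable.
    """
    if isinstance(events, pd.DataFrame):
        values = events["min_ir_io"].to_numpy(float) if not events.empty else np.array([])
    else:
        values = np.asarray(list(events), float)
    counts, _ = np.histogram(values, bins=BIN_EDGES)
    return _histogram_from_counts(counts, count_mode)


def ratio_R(hist: BlockadeHistogram) -> float:
    """R = late-maximum count / early-maximum count."""
    if hist.early_count <= 0:
        raise UndefinedRatioError("no events under the early maximum; R undefined")
    return hist.late_count / hist.early_count


def classify(buffer_R: float, sample_R: float, significance: float = 0.18) -> str:
    """Detection iff R dropped by more than the significance fraction."""
    if buffer_R <= 0:
        raise ValueError("buffer R must be positive")
    change = (sample_R - buffer_R) / buffer_R
    # detection requires *more* than the significance change; the tiny slack
    # keeps an exactly-at-threshold drop from flipping on float round-off
    return "detection" if change < -significance - 1e-9 else "silencing"


def run_result_from_events(
    events: pd.DataFrame,
    run_kind: str,
    params: DecisionParams = DecisionParams(),
) -> RunResult:
    """Channel-QC one run's event table and summarise it."""
    filtered, removed = qc_filter_channels(events, params.channel_event_cap)
    hist = build_histogram(filtered, params.count_mode)
    try:
        r = ratio_R(hist)
    except UndefinedRatioError:
        r = None
    active = int(filtered["channel"].nunique()) if not filtered.empty else 0
    return RunResult(
        run_kind=run_kind,
        histogram=hist,
        R=r,
        active_channels=active,
        total_events=int(len(filtered)),
        removed_channels=removed,
    )


def _shift_ok(hist: BlockadeHistogram, max_shift: float) -> bool:
    for peak, nominal in ((hist.early_peak, EARLY_NOMINAL), (hist.late_peak, LATE_NOMINAL)):
        if peak is not None and abs(peak - nominal) > max_shift + 1e-9:
            return False
    return True


def run_yenos_test(
    buffer_events: list[pd.DataFrame],
    sample_events: list[pd.DataFrame],
    params: DecisionParams = DecisionParams(),
    extra_sample_events: pd.DataFrame | None = None,
) -> YenosTestResult:
    """Decide one test from two buffer and two sample event tables.

    The buffer histograms are pooled (counts added); each sample run is
    classified against the pooled buffer R, and a call is issued only when
    the sample runs agree.  An optional third sample run breaks ties.
    Rejection rules, in the order checked: too few active pores, gross
    sample event excess, blockade-maximum drift beyond +/-max_shift,
    undefined R, and sample-run disagreement.
    """
    if len(buffer_events) != 2 or len(sample_events) != 2:
        raise ValueError("expected exactly two buffer and two sample event tables")

    buffer_runs = [run_result_from_events(e, "buffer", params) for e in buffer_events]
    sample_runs = [run_result_from_events(e, "sample", params) for e in sample_events]
    all_runs = buffer_runs + sample_runs

    pooled_counts = buffer_runs[0].histogram.counts + buffer_runs[1].histogram.counts
    pooled = _histogram_from_counts(pooled_counts, params.count_mode)
    pooled_R = ratio_R(pooled) if pooled.early_count > 0 else None
    changes = [
        (run.R - pooled_R) / pooled_R if (run.R is not None and pooled_R) else float("nan")
        for run in sample_runs
    ]

    def rejected(reason):
        return YenosTestResult(buffer_runs, sample_runs, pooled_R, changes, "rejected", reason)

    if min(r.active_channels for r in all_runs) <= params.min_active_channels:
        return rejected("too_few_pores")
    buffer_total = sum(r.total_events for r in buffer_runs)
    sample_total = sum(r.total_events for r in sample_runs)
    if buffer_total > 0 and sample_total > params.excess_factor * buffer_total:
        return rejected("event_excess")
    if not all(_shift_ok(r.histogram, params.max_shift) for r in all_runs):
        return rejected("max_shift")
    if pooled_R is None or any(run.R is None for run in sample_runs):
        return rejected("undefined_R")

    calls = [classify(pooled_R, run.R, params.significance) for run in sample_runs]
    if calls[0] == calls[1]:
        return YenosTestResult(buffer_runs, sample_runs, pooled_R, changes, calls[0], "none")
    if extra_sample_events is not None:
        third = run_result_from_events(extra_sample_events, "sample", params)
        if third.R is not None:
            tie_break = classify(pooled_R, third.R, params.significance)
            sample_runs.append(third)
            changes.append((third.R - pooled_R) / pooled_R)
            return YenosTestResult(buffer_runs, sample_runs, pooled_R, changes, tie_break, "none")
    return rejected("disagreement")


def _histogram_from_counts(counts: np.ndarray, count_mode: str = "modal") -> BlockadeHistogram:
    hist = BlockadeHistogram(counts=np.asarray(counts, np.int64))
    if hist.total == 0:
        return hist
    for window, which in ((EARLY_WINDOW, "early"), (LATE_WINDOW, "late")):
        sl = _window_slice(window)
        wc = hist.counts[sl]
        k = int(np.argmax(wc))  # argmax ties break toward the lower bin
        bin_label = float(BIN_LABELS[sl[k]])
        count = int(wc.sum() if count_mode == "window_sum" else wc[k])
        if which == "early":
            hist.early_max_bin, hist.early_count = bin_label, count
        else:
            hist.late_max_bin, hist.late_count = bin_label, count
    hist.early_peak, hist.late_peak = _locate_peaks(hist.counts)
    return hist
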