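import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


def make_event_frame(values, channels=300, duration=10):
    """Event table with the given min Ir/Io values spread over channels."""
    values = np.asarray(values, float)
    n = values.size
    ch = np.arange(n) % channels + 1
    return pd.DataFrame(
        {
            "channel": ch,
            "start_tp": np.arange(n, dtype=np.int64),
            "duration_tps": np.full(n, duration, dtype=np.int64),
            "min_ir_io": values,
            "mean_ir_io": values,
        }
    )


def two_spike_run(early, late, channels=300, early_val=0.16, late_val=0.31):
    """A run whose histogram has `early` events at ~0.15 and `late` at ~0.30."""
    vals = np.r_[np.full(early, early_val), np.full(late, late_val)]
    return make_event_frame(vals, channels=channels)
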