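import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from divechaos import (DepthRecord, EmbeddingParams, SimConfig,
                       simulate_dive_record)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130815)


@pytest.fixture(scope="session")
def short_record():
    """Six hours of default-grammar diving, enough for a few bouts."""
    rec, trace = simulate_dive_record(SimConfig(), 6 * 3600.0, seed=11)
    return rec, trace


@pytest.fixture(scope="session")
def day_record():
    rec, trace = simulate_dive_record(SimConfig(), 86400.0, seed=5)
    return rec, trace


@pytest.fixture()
def ramp_record():
    """Deterministic 1 m/s descent for 100 s."""
    return DepthRecord(t0="2013-08-15", dt=1.0, depth=np.arange(100.0))


@pytest.fixture(scope="session")
def default_params():
    return EmbeddingParams(tau_s=300.0, m=3, dt=1.0)


def make_labels(n=40, tags=("deep-bout", "shallow-bout", "intermediate",
                            "near-surface-shallow"), t0="2013-09-01",
                step_min=10, confidence=1.0):
    """Synthetic LabeledWindows table cycling through the given tags."""
    times = pd.date_range(t0, periods=n, freq=f"{step_min}min", tz="UTC")
    tag_list = [tags[i % len(tags)] for i in range(n)]
    return pd.DataFrame({
        "window_start": times,
        "window_mid": times + pd.Timedelta(minutes=15),
        "cluster": [i % len(tags) for i in range(n)],
        "confidence": confidence,
        "tag": tag_list,
    })
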