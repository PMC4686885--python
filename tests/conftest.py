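import numpy as np
import pytest
from hypothesis import settings

from pupilvalence import PupilTrace, SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_trace(
    t,
    d,
    subject="s01",
    trial="t01",
    label="positive",
    sampling_rate=None,
    stimulus_duration=None,
    pd_right=None,
):
    """Build a trace whose both eyes carry ``d`` (NaN = missing sample)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    right = d if pd_right is None else np.asarray(pd_right, dtype=float)
    if sampling_rate is None:
        sampling_rate = 1.0 / np.median(np.diff(t))
    if stimulus_duration is None:
        stimulus_duration = float(max(t.max(), 0.0))
    return PupilTrace(
        subject=subject,
        trial=trial,
        label=label,
        sampling_rate=float(sampling_rate),
        stimulus_duration=stimulus_duration,
        t=t,
        pd_left=d.copy(),
        pd_right=right.copy(),
        valid_left=np.isfinite(d),
        valid_right=np.isfinite(right),
    )


@pytest.fixture
def small_cfg():
    """A scaled-down cohort config for fast unit tests (60 Hz, 6 subjects)."""
    return SimConfig(n_subjects=6, trials_per_valence=3, sampling_rate=60.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
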