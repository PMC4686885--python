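import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilvalence import (
    CleanSignal,
    DataError,
    ParameterError,
    average_by_valence,
    average_eyes,
    baseline_correct,
    filter_and_interpolate,
    missing_fraction,
    smooth,
)
from pupilvalence.simulate import SimConfig, simulate_trial

from conftest import make_trace


def interp_oracle(t, d):
    """Plain piecewise-linear gap filling, written independently as a loop."""
    out = d.copy()
    good = np.flatnonzero(np.isfinite(d))
    for i in range(len(d)):
        if np.isfinite(d[i]):
            continue
        left = good[good < i]
        right = good[good > i]
        if left.size and right.size:
            lo, hi = left[-1], right[0]
            frac = (t[i] - t[lo]) / (t[hi] - t[lo])
            out[i] = d[lo] + frac * (d[hi] - d[lo])
        elif left.size:
            out[i] = d[left[-1]]
        else:
            out[i] = d[right[0]]
    return out


class TestAverageEyes:
    def test_mean_of_two_valid_eyes(self):
        tr = make_trace([0.0, 0.5], [4.0, 4.0], pd_right=[4.2, 4.2])
        assert average_eyes(tr).d == pytest.approx([4.1, 4.1])

    def test_single_eye_fallback_and_double_missing(self):
        tr = make_trace([0.0, 0.5], [4.0, np.nan], pd_right=[np.nan, np.nan])
        d = average_eyes(tr).d
        assert d[0] == 4.0 and np.isnan(d[1])

    def test_invalid_flag_excludes_eye(self):
        tr = make_trace([0.0, 0.5], [4.0, 4.0], pd_right=[5.0, 5.0])
        tr.valid_right[:] = False
        assert average_eyes(tr).d == pytest.approx([4.0, 4.0])


class TestMissingFraction:
    def test_extremes_and_quarter(self):
        t = np.arange(12) * 0.5 - 1.0  # covers [-1, 4.5]
        full = make_trace(t, np.full(12, 4.0), stimulus_duration=4.5)
        assert missing_fraction(average_eyes(full)) == 0.0
        empty = make_trace(t, np.full(12, np.nan), stimulus_duration=4.5)
        assert missing_fraction(average_eyes(empty)) == 1.0
        d = np.full(12, 4.0)
        d[[2, 5, 9]] = np.nan
        assert missing_fraction(average_eyes(make_trace(t, d, stimulus_duration=4.5))) == 0.25

    def test_pre_window_samples_outside_analysis_ignored(self):
        t = np.arange(-3.0, 1.01, 0.5)
        d = np.full(t.size, 4.0)
        d[t < -1] = np.nan  # missing only before the analysis window
        tr = make_trace(t, d, stimulus_duration=1.0)
        assert missing_fraction(average_eyes(tr)) == 0.0


class TestFilterAndInterpolate:
    def test_midpoint_fill(self):
        tr = average_eyes(make_trace([0.0, 0.5, 1.0], [4.0, np.nan, 5.0]))
        (out,) = filter_and_interpolate([tr])
        assert out.d == pytest.approx([4.0, 4.5, 5.0])

    def test_mostly_missing_trial_dropped(self):
        t = np.arange(10) * 0.5
        d = np.full(10, 4.0)
        d[:6] = np.nan  # 60% missing
        assert filter_and_interpolate([average_eyes(make_trace(t, d))] ) == []

    def test_threshold_is_strict(self):
        t = np.arange(10) * 0.5
        d = np.full(10, 4.0)
        d[:5] = np.nan  # exactly 50%: retained
        out = filter_and_interpolate([average_eyes(make_trace(t, d))])
        assert len(out) == 1 and np.all(np.isfinite(out[0].d))

    @given(st.data())
    @settings(deadline=None, max_examples=30)
    def test_matches_oracle_and_preserves_valid_samples(self, data):
        n = data.draw(st.integers(6, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        t = np.arange(n) * 0.1
        d = 4.0 + rng.normal(0, 0.3, n).cumsum() * 0.05
        d = np.clip(d, 1.0, 9.0)
        gaps = rng.random(n) < 0.3
        gaps[rng.integers(n)] = False  # keep at least one valid sample
        d[gaps] = np.nan
        tr = average_eyes(make_trace(t, d))
        if missing_fraction(tr) > 0.5:
            return
        (out,) = filter_and_interpolate([tr])
        assert out.d == pytest.approx(interp_oracle(t, d), nan_ok=False)
        assert out.d[~gaps] == pytest.approx(d[~gaps])  # valid samples untouched


class TestSmooth:
    def test_constant_invariance(self):
        assert smooth(np.full(20, 3.3)) == pytest.approx(np.full(20, 3.3))

    def test_linear_ramp_interior_unchanged(self):
        x = np.linspace(0, 1, 25)
        assert smooth(x)[3:-3] == pytest.approx(x[3:-3])

    def test_unit_impulse_spreads_to_one_seventh(self):
        x = np.zeros(21)
        x[10] = 1.0
        out = smooth(x, span=7)
        assert out[7:14] == pytest.approx(np.full(7, 1 / 7))
        assert out[[6, 14]] == pytest.approx([0.0, 0.0])

    def test_even_span_rejected(self):
        with pytest.raises(ParameterError):
            smooth(np.zeros(10), span=4)

    def test_edges_use_shrinking_symmetric_windows(self):
        x = np.arange(9.0)
        out = smooth(x, span=5)
        assert out[0] == x[0]
        assert out[1] == pytest.approx(x[:3].mean())

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    @settings(deadline=None)
    def test_output_bounded_by_input(self, values):
        x = np.array(values)
        out = smooth(x)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12


class TestBaselineCorrect:
    @staticmethod
    def flat_trace(value=4.0):
        t = np.arange(-3.0, 2.001, 0.1)
        tr = average_eyes(make_trace(t, np.full(t.size, value), stimulus_duration=2.0))
        return tr

    def test_subtract_mode_zeroes_constant(self):
        sig = baseline_correct(self.flat_trace(), "subtract_200ms")
        assert sig.d == pytest.approx(np.zeros(sig.d.size))
        assert sig.baseline == pytest.approx(4.0)

    def test_reference_mode_stores_mean_keeps_signal(self):
        sig = baseline_correct(self.flat_trace(), "reference")
        assert sig.baseline == pytest.approx(4.0)
        assert sig.d == pytest.approx(np.full(sig.d.size, 4.0))

    def test_simulated_trial_matches_hand_computed_mean(self, rng):
        cfg = SimConfig(sampling_rate=60.0, blink_rate=0.0, missing_fraction=0.0)
        tr = average_eyes(simulate_trial("negative", 0.1, cfg, rng))
        sig = baseline_correct(tr, "reference")
        pre = (tr.t >= -3.0) & (tr.t < 0)
        assert sig.baseline == pytest.approx(tr.d[pre].mean())
        sub = baseline_correct(tr, "subtract_200ms")
        pre200 = (tr.t >= -0.2) & (tr.t < 0)
        assert sub.d == pytest.approx(tr.d - tr.d[pre200].mean())

    def test_insufficient_prestimulus_data_rejected(self):
        t = np.arange(-1.0, 2.001, 0.1)  # only 1 s of pre-stimulus
        tr = average_eyes(make_trace(t, np.full(t.size, 4.0), stimulus_duration=2.0))
        with pytest.raises(DataError, match="pre-stimulus"):
            baseline_correct(tr, "reference")
        baseline_correct(tr, "subtract_200ms")  # 200 ms is available


class TestAverageByValence:
    @staticmethod
    def signal(d, subject="s01", label="positive"):
        d = np.asarray(d, dtype=float)
        t = np.arange(d.size) * 0.1
        return CleanSignal(subject, label, 10.0, t, d, 4.0, "reference")

    def test_idempotent_on_identical_trials(self):
        s = self.signal([4.0, 4.2, 4.1])
        (out,) = average_by_valence([s, s.copy()])
        assert out.d == pytest.approx(s.d)

    def test_symmetric_trials_cancel(self):
        up = self.signal([1.0, 2.0, 3.0])
        down = self.signal([-1.0, -2.0, -3.0])
        (out,) = average_by_valence([up, down])
        assert out.d == pytest.approx(np.zeros(3))

    def test_matches_pointwise_mean(self, rng):
        trials = [self.signal(4 + rng.normal(0, 0.1, 8)) for _ in range(5)]
        (out,) = average_by_valence(trials)
        assert out.d == pytest.approx(np.mean([s.d for s in trials], axis=0))

    def test_groups_by_subject_and_label(self):
        sigs = [
            self.signal([4.0], "s02", "negative"),
            self.signal([4.0], "s01", "positive"),
            self.signal([4.0], "s01", "negative"),
        ]
        out = average_by_valence(sigs)
        assert [(s.subject, s.label) for s in out] == [
            ("s01", "negative"),
            ("s01", "positive"),
            ("s02", "negative"),
        ]

    def test_mismatched_grids_rejected(self):
        a = self.signal([4.0, 4.1])
        b = CleanSignal("s01", "positive", 10.0, [0.05, 0.15], [4.0, 4.1], 4.0, "reference")
        with pytest.raises(DataError, match="grid"):
            average_by_valence([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            average_by_valence([])


def test_pipeline_yields_at_most_two_signals_per_subject(small_cfg):
    from pupilvalence.cli import preprocess_traces
    from pupilvalence.simulate import simulate_cohort

    signals, _ = preprocess_traces(simulate_cohort(small_cfg), "reference")
    per_subject = {}
    for s in signals:
        per_subject.setdefault(s.subject, set()).add(s.label)
    for labels in per_subject.values():
        assert labels <= {"positive", "negative"} and 1 <= len(labels) <= 2
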