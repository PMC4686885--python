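"""Last-second feature extraction from cleaned pupil signals.

Three analysis windows are defined relative to stimulus onset: T_before =
(-1, 0) s, T_after = (0, T_end) s with T_end the analyzed stimulus duration
(6 s for the sound protocol, 5 s for the word protocol), and T_critical =
(T_end - 1, T_end) s, the final post-stimulus second where the difference
between positive and negative responses is largest.

Six features summarise each per-subject, per-valence averaged signal D(t):

f1  max dilation          max of D over T_after                       [mm]
f2  accumulated velocity  max over T_after of the running velocity
                          integral (anchored at the start of T_before)
                          minus the same max over T_before             [mm]
f3  velocity change       max of V over T_after minus mean of V
                          over T_before                               [mm/s]
f4  critical dilation     max of D over T_critical                     [mm]
f5  area change           max of pupil area pi*(D/2)^2 over
                          T_after beyond 0.2 s minus its mean
                          over T_before                              [mm^2]
f6  gradient change       max of the central-difference gradient over
                          T_after minus its mean over T_before        [mm/s]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataError
from .preprocess import CleanSignal

#: Start of the after-window portion used by the area feature (seconds).
AREA_ONSET_OFFSET = 0.2


@dataclass(frozen=True)
class WindowSpec:
    """The three analysis windows, each an (open-left, closed-right] interval."""

    before: tuple[float, float] = (-1.0, 0.0)
    after: tuple[float, float] = (0.0, 6.0)
    critical: tuple[float, float] = (5.0, 6.0)

    def __post_init__(self) -> None:
        if not (self.after[0] <= self.critical[0] < self.critical[1] <= self.after[1]):
            raise DataError("critical window must lie inside the after window")
        if self.before[1] > self.after[0]:
            raise DataError("before window must precede stimulus onset")

    @classmethod
    def for_duration(cls, t_end: float) -> "WindowSpec":
        """Standard windows for an analyzed duration of ``t_end`` seconds."""
        return cls(before=(-1.0, 0.0), after=(0.0, t_end), critical=(t_end - 1.0, t_end))


@dataclass(frozen=True)
class FeatureVector:
    """The six per-signal features; see the module docstring for units."""

    f1_max_dilation: float
    f2_max_accumulated_velocity_change: float
    f3_max_velocity_change: float
    f4_max_critical_dilation: float
    f5_area_change: float
    f6_gradient_change: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.f1_max_dilation,
                self.f2_max_accumulated_velocity_change,
                self.f3_max_velocity_change,
                self.f4_max_critical_dilation,
                self.f5_area_change,
                self.f6_gradient_change,
            ]
        )


FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6")


def velocity(d: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Backward-difference pupil velocity in mm/s; the first point is 0."""
    d = np.asarray(d, dtype=float)
    if d.size < 2:
        raise DataError("velocity needs at least 2 samples")
    v = np.empty_like(d)
    v[0] = 0.0
    v[1:] = np.diff(d) * sampling_rate
    return v


def area(d: np.ndarray) -> np.ndarray:
    """Pupil area pi*(D/2)^2 in mm^2 from a diameter series in mm."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DataError("pupil area requires strictly positive diameters")
    return np.pi * (d / 2.0) ** 2


def gradient1d(d: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Temporal gradient in mm/s: central differences inside, one-sided at the ends."""
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        raise DataError("gradient1d needs at least 3 samples")
    return np.gradient(d, 1.0 / sampling_rate)


def _masks(signal: CleanSignal, w: WindowSpec):
    t = signal.t
    before = (t > w.before[0]) & (t < w.before[1])
    after = (t > w.after[0]) & (t <= w.after[1])
    critical = (t > w.critical[0]) & (t <= w.critical[1])
    return before, after, critical


def extract_features(signal: CleanSignal, w: WindowSpec) -> FeatureVector:
    """Compute the six features of one cleaned signal over windows ``w``.

    Raises :class:`DataError` when the signal does not cover all three
    windows.  The velocity integral of f2 is multiplied by the sample
    spacing, so its value is a displacement in mm and does not depend on the
    sampling rate.
    """
    before, after, critical = _masks(signal, w)
    area_after = after & (signal.t > w.after[0] + AREA_ONSET_OFFSET)
    for name, mask in (
        ("before", before),
        ("after", after),
        ("critical", critical),
        ("area after", area_after),
    ):
        if not mask.any():
            raise DataError(f"signal does not cover the {name} window")
    d = signal.d
    dt = 1.0 / signal.sampling_rate

    f1 = float(d[after].max())
    f4 = float(d[critical].max())

    v = velocity(d, signal.sampling_rate)
    # running integral of V anchored at the first sample of T_before
    i0 = int(np.flatnonzero(before)[0])
    integral = np.full(d.size, np.nan)
    integral[i0:] = np.cumsum(v[i0:]) * dt
    f2 = float(np.nanmax(integral[after]) - np.nanmax(integral[before]))
    f3 = float(v[after].max() - v[before].mean())

    ar = area(d)
    f5 = float(ar[area_after].max() - ar[before].mean())

    g = gradient1d(d, signal.sampling_rate)
    f6 = float(g[after].max() - g[before].mean())

    return FeatureVector(f1, f2, f3, f4, f5, f6)


@dataclass
class LabeledFeatureMatrix:
    """Feature rows with aligned valence labels and subject ids.

    Rows are ordered deterministically by (subject, label); with the full
    30-subject two-valence design the matrix is 60 x 6.
    """

    X: np.ndarray
    labels: list[str]
    subjects: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise DataError("feature matrix must be n x 6")
        if self.X.shape[0] != len(self.labels) or len(self.labels) != len(self.subjects):
            raise DataError("labels/subjects must align with matrix rows")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "LabeledFeatureMatrix":
        idx = np.asarray(idx, dtype=int)
        return LabeledFeatureMatrix(
            X=self.X[idx],
            labels=[self.labels[i] for i in idx],
            subjects=[self.subjects[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(FEATURE_NAMES))
        df.insert(0, "label", self.labels)
        df.insert(0, "subject", self.subjects)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LabeledFeatureMatrix":
        df = pd.read_csv(path, dtype={"subject": str})
        return cls(
            X=df[list(FEATURE_NAMES)].to_numpy(float),
            labels=df["label"].tolist(),
            subjects=df["subject"].tolist(),
        )


def build_matrix(signals, w: WindowSpec) -> LabeledFeatureMatrix:
    """Extract features from every signal and stack them into a labeled matrix.

    Input order is irrelevant: rows are sorted by (subject, label).  At least
    two signals from at least two classes are required.
    """
    signals = sorted(signals, key=lambda s: (s.subject, s.label))
    if len(signals) < 2:
        raise DataError("need at least two signals to build a feature matrix")
    if len({s.label for s in signals}) < 2:
        raise DataError("feature matrix needs at least two classes")
    rows = [extract_features(s, w).as_array() for s in signals]
    return LabeledFeatureMatrix(
        X=np.vstack(rows),
        labels=[s.label for s in signals],
        subjects=[s.subject for s in signals],
    )
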