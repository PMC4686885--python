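"""Readers and writers for pupil traces, affect ratings, and derived tables.

The on-disk trace dialect is a tab-separated text file with a header row,
one sample per line, resembling a generic eye-tracker export: per-eye pupil
diameters in millimetres, per-eye validity flags, and time in seconds
relative to stimulus onset (negative = pre-stimulus).  Missing diameters are
written as empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

VALENCE_LABELS = ("positive", "negative", "neutral")

#: Positive PANAS-X basic affects averaged into the basic-positive score.
POSITIVE_AFFECTS = ("joviality", "self_assurance", "attentiveness")
#: Negative PANAS-X basic affects averaged into the basic-negative score.
NEGATIVE_AFFECTS = ("fear", "sadness", "guilt", "hostility")

TRACE_COLUMNS = (
    "subject",
    "trial",
    "label",
    "sampling_rate",
    "stimulus_duration",
    "t",
    "pd_left",
    "pd_right",
    "valid_left",
    "valid_right",
)


@dataclass(frozen=True)
class TraceDialect:
    """On-disk dialect for trace tables: separator and missing-value token."""

    sep: str = "\t"
    na_rep: str = ""


@dataclass
class PupilTrace:
    """One trial's time-stamped pupil-diameter series with validity flags.

    Parameters
    ----------
    subject, trial : str
        Identifiers; one trace per (subject, trial).
    label : str
        Stimulus valence: ``positive``, ``negative`` or ``neutral``.
    sampling_rate : float
        Hz; the time grid is assumed uniform at this rate.
    stimulus_duration : float
        Seconds of post-onset signal that are analyzed.
    t : ndarray
        Seconds relative to stimulus onset, strictly increasing.
    pd_left, pd_right : ndarray
        Per-eye diameters in mm; NaN where the sample is missing.
    valid_left, valid_right : ndarray of bool
        Tracker validity flags; an eye's sample counts only if flagged valid
        and finite.
    d : ndarray or None
        Combined single diameter channel, set by
        :func:`pupilvalence.preprocess.average_eyes`.
    """

    subject: str
    trial: str
    label: str
    sampling_rate: float
    stimulus_duration: float
    t: np.ndarray
    pd_left: np.ndarray
    pd_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pd_left = np.asarray(self.pd_left, dtype=float)
        self.pd_right = np.asarray(self.pd_right, dtype=float)
        self.valid_left = np.asarray(self.valid_left, dtype=bool)
        self.valid_right = np.asarray(self.valid_right, dtype=bool)
        if self.label not in VALENCE_LABELS:
            raise DataError(
                f"label {self.label!r} not in {VALENCE_LABELS} "
                f"(subject={self.subject}, trial={self.trial})"
            )
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise DataError(
                f"time not strictly increasing in trial "
                f"(subject={self.subject}, trial={self.trial})"
            )
        for name, arr in (("pd_left", self.pd_left), ("pd_right", self.pd_right)):
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() <= 0 or vals.max() >= 10):
                raise DataError(f"{name} outside the physiological (0, 10) mm range")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def copy(self, **changes) -> "PupilTrace":
        kwargs = dict(
            t=self.t.copy(),
            pd_left=self.pd_left.copy(),
            pd_right=self.pd_right.copy(),
            valid_left=self.valid_left.copy(),
            valid_right=self.valid_right.copy(),
            d=None if self.d is None else self.d.copy(),
        )
        kwargs.update(changes)
        return replace(self, **kwargs)

    def __eq__(self, other) -> bool:  # NaN-aware array equality
        if not isinstance(other, PupilTrace):
            return NotImplemented
        scalars = ("subject", "trial", "label", "sampling_rate", "stimulus_duration")
        if any(getattr(self, f) != getattr(other, f) for f in scalars):
            return False
        for f in ("t", "pd_left", "pd_right", "valid_left", "valid_right"):
            if not np.array_equal(getattr(self, f), getattr(other, f), equal_nan=True):
                return False
        return True


@dataclass
class RatingRecord:
    """One trial's PANAS-X basic-affect ratings on a 1-5 scale."""

    subject: str
    trial: str
    joviality: float
    self_assurance: float
    attentiveness: float
    fear: float
    sadness: float
    guilt: float
    hostility: float
    neutral: bool = False

    scores: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores = {
            a: getattr(self, a) for a in POSITIVE_AFFECTS + NEGATIVE_AFFECTS
        }
        for affect, value in self.scores.items():
            if value is None or not np.isfinite(value):
                raise DataError(
                    f"missing {affect} score (subject={self.subject}, trial={self.trial})"
                )
            if not 1 <= value <= 5:
                raise DataError(f"{affect}={value} outside the 1-5 rating scale")


def read_trace_table(path, dialect: TraceDialect = TraceDialect()) -> list[PupilTrace]:
    """Read a trace table; returns one :class:`PupilTrace` per (subject, trial).

    Raises :class:`FormatError` if a required column is absent and
    :class:`DataError` if time is non-monotone within a trial.
    """
    df = pd.read_csv(
        path, sep=dialect.sep, dtype={"subject": str, "trial": str},
        float_precision="round_trip",
    )
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace table {path} lacks required column(s): {missing}")
    traces = []
    for (subject, trial), g in df.groupby(["subject", "trial"], sort=True):
        labels = g["label"].unique()
        if len(labels) != 1:
            raise DataError(f"trial ({subject}, {trial}) has mixed labels {labels}")
        traces.append(
            PupilTrace(
                subject=subject,
                trial=trial,
                label=str(labels[0]),
                sampling_rate=float(g["sampling_rate"].iloc[0]),
                stimulus_duration=float(g["stimulus_duration"].iloc[0]),
                t=g["t"].to_numpy(float),
                pd_left=g["pd_left"].to_numpy(float),
                pd_right=g["pd_right"].to_numpy(float),
                valid_left=g["valid_left"].to_numpy(bool),
                valid_right=g["valid_right"].to_numpy(bool),
            )
        )
    return traces


def write_trace_table(traces, path, dialect: TraceDialect = TraceDialect()) -> None:
    """Write traces to ``path``; inverse of :func:`read_trace_table`."""
    traces = list(traces)
    if not traces:
        raise DataError("cannot write an empty trace collection")
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "subject": tr.subject,
                    "trial": tr.trial,
                    "label": tr.label,
                    "sampling_rate": tr.sampling_rate,
                    "stimulus_duration": tr.stimulus_duration,
                    "t": tr.t,
                    "pd_left": tr.pd_left,
                    "pd_right": tr.pd_right,
                    "valid_left": tr.valid_left.astype(int),
                    "valid_right": tr.valid_right.astype(int),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)[list(TRACE_COLUMNS)]
    # %.17g guarantees an exact binary round-trip of every float
    out.to_csv(
        path, sep=dialect.sep, index=False, na_rep=dialect.na_rep,
        float_format="%.17g",
    )


RATING_COLUMNS = ("subject", "trial") + POSITIVE_AFFECTS + NEGATIVE_AFFECTS


def read_rating_table(path) -> list[RatingRecord]:
    """Read a comma-separated ratings table into :class:`RatingRecord` rows."""
    df = pd.read_csv(path, dtype={"subject": str, "trial": str})
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"rating table {path} lacks required column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            RatingRecord(
                subject=row["subject"],
                trial=row["trial"],
                neutral=bool(row.get("neutral", False)),
                **{a: float(row[a]) for a in POSITIVE_AFFECTS + NEGATIVE_AFFECTS},
            )
        )
    return records


def aggregate_panas(record: RatingRecord) -> tuple[float, float]:
    """Collapse the seven basic-affect ratings into (basic_positive, basic_negative).

    Basic positive affect is the mean of joviality, self-assurance and
    attentiveness; basic negative affect is the mean of fear, sadness,
    guilt and hostility.
    """
    basic_positive = float(np.mean([record.scores[a] for a in POSITIVE_AFFECTS]))
    basic_negative = float(np.mean([record.scores[a] for a in NEGATIVE_AFFECTS]))
    return basic_positive, basic_negative


def label_trial(record: RatingRecord) -> str:
    """Assign a valence label from the aggregated PANAS-X scores.

    Positive if basic-positive exceeds basic-negative, negative for the
    reverse, neutral on an exact tie or when the rater flagged the trial
    as neutral explicitly.
    """
    if record.neutral:
        return "neutral"
    basic_positive, basic_negative = aggregate_panas(record)
    if basic_positive > basic_negative:
        return "positive"
    if basic_negative > basic_positive:
        return "negative"
    return "neutral"


def write_signal_table(signals, path, dialect: TraceDialect = TraceDialect()) -> None:
    """Write cleaned signals (one row per grid point) as tab-separated text."""
    from .preprocess import CleanSignal  # deferred: preprocess imports io

    signals = list(signals)
    if not signals:
        raise DataError("cannot write an empty signal collection")
    frames = []
    for s in signals:
        assert isinstance(s, CleanSignal)
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "label": s.label,
                    "sampling_rate": s.sampling_rate,
                    "baseline": s.baseline,
                    "baseline_mode": s.baseline_mode,
                    "t": s.t,
                    "d": s.d,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep=dialect.sep, index=False, na_rep=dialect.na_rep,
        float_format="%.17g",
    )


def read_signal_table(path, dialect: TraceDialect = TraceDialect()):
    """Read a signal table written by :func:`write_signal_table`."""
    from .preprocess import CleanSignal

    df = pd.read_csv(
        path, sep=dialect.sep, dtype={"subject": str},
        float_precision="round_trip",
    )
    required = ("subject", "label", "sampling_rate", "baseline", "baseline_mode", "t", "d")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"signal table {path} lacks required column(s): {missing}")
    signals = []
    for (subject, label), g in df.groupby(["subject", "label"], sort=True):
        signals.append(
            CleanSignal(
                subject=subject,
                label=str(label),
                sampling_rate=float(g["sampling_rate"].iloc[0]),
                baseline=float(g["baseline"].iloc[0]),
                baseline_mode=str(g["baseline_mode"].iloc[0]),
                t=g["t"].to_numpy(float),
                d=g["d"].to_numpy(float),
            )
        )
    return signals
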