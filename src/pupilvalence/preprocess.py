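"""Preprocessing of raw pupil traces.

The cleaning chain turns per-eye raw recordings into per-subject,
per-valence averaged signals:

1. :func:`average_eyes` — collapse left/right diameters into one channel;
2. :func:`filter_and_interpolate` — drop trials with more than half of the
   analysis window missing (blinks, tracking loss) and linearly interpolate
   the gaps of the retained trials;
3. :func:`smooth` — centred moving average (default span 7 samples) to
   improve signal-to-noise ratio;
4. :func:`baseline_correct` — reference each trial to its pre-stimulus mean,
   either stored alongside the absolute trace (``reference``) or subtracted
   from it (``subtract_200ms``);
5. :func:`average_by_valence` — pointwise mean of a subject's trials of the
   same valence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DataError, ParameterError
from .io import PupilTrace

#: Fraction of missing samples above which a trial is discarded.
DEFAULT_MISSING_DROP_THRESHOLD = 0.5
#: Default moving-average span in samples (must be odd).
DEFAULT_SMOOTH_SPAN = 7

#: Pre-stimulus windows (seconds before onset) used by the two baseline modes.
BASELINE_WINDOWS = {"reference": 3.0, "subtract_200ms": 0.2}


@dataclass
class CleanSignal:
    """A gap-free, baseline-referenced diameter series on a uniform grid.

    ``baseline_mode='reference'`` stores the pre-stimulus mean in
    ``baseline`` and keeps ``d`` in absolute mm; ``'subtract_200ms'``
    subtracts the 200 ms pre-stimulus mean from ``d`` and stores that mean
    so the absolute trace remains recoverable.
    """

    subject: str
    label: str
    sampling_rate: float
    t: np.ndarray
    d: np.ndarray
    baseline: float
    baseline_mode: str
    trial: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.t.shape != self.d.shape:
            raise DataError("t and d must have equal length")
        if np.any(~np.isfinite(self.d)):
            raise DataError("CleanSignal may not contain missing values")

    def copy(self, **changes) -> "CleanSignal":
        kwargs = dict(t=self.t.copy(), d=self.d.copy())
        kwargs.update(changes)
        return replace(self, **kwargs)


def _combined_diameter(trace: PupilTrace) -> np.ndarray:
    left = np.where(trace.valid_left & np.isfinite(trace.pd_left), trace.pd_left, np.nan)
    right = np.where(
        trace.valid_right & np.isfinite(trace.pd_right), trace.pd_right, np.nan
    )
    both = np.stack([left, right])
    good = np.isfinite(both)
    count = good.sum(axis=0)
    total = np.where(good, both, 0.0).sum(axis=0)
    return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def average_eyes(trace: PupilTrace) -> PupilTrace:
    """Collapse both eyes into a single diameter channel.

    Per sample the combined diameter is the mean of the valid eyes; with one
    valid eye that eye is used alone; with neither, the sample is missing
    (NaN).  Returns a copy with the ``d`` channel set.
    """
    out = trace.copy()
    out.d = _combined_diameter(trace)
    return out


def _analysis_mask(trace: PupilTrace) -> np.ndarray:
    return (trace.t >= -1.0) & (trace.t <= trace.stimulus_duration)


def missing_fraction(trace: PupilTrace) -> float:
    """Fraction of missing samples within the analysis window [-1 s, T_end]."""
    if trace.n_samples == 0:
        raise DataError("empty trace")
    d = trace.d if trace.d is not None else _combined_diameter(trace)
    window = d[_analysis_mask(trace)]
    if window.size == 0:
        raise DataError("trace has no samples in the analysis window")
    return float(np.mean(~np.isfinite(window)))


def filter_and_interpolate(
    traces, drop_threshold: float = DEFAULT_MISSING_DROP_THRESHOLD
) -> list[PupilTrace]:
    """Drop heavily corrupted trials and close the gaps of the rest.

    Trials whose analysis window is more than ``drop_threshold`` missing are
    removed.  In retained trials every missing run is filled by linear
    interpolation between its nearest valid neighbours; missing runs at the
    ends are extended with the nearest valid value.  Valid samples are never
    altered.
    """
    out = []
    for trace in traces:
        if missing_fraction(trace) > drop_threshold:
            continue
        tr = trace if trace.d is not None else average_eyes(trace)
        d = tr.d.copy()
        good = np.isfinite(d)
        if not good.any():
            raise DataError(
                f"retained trace has no valid samples "
                f"(subject={trace.subject}, trial={trace.trial})"
            )
        if not good.all():
            d[~good] = np.interp(tr.t[~good], tr.t[good], d[good])
        filled = tr.copy()
        filled.d = d
        out.append(filled)
    return out


def smooth(x: np.ndarray, span: int = DEFAULT_SMOOTH_SPAN) -> np.ndarray:
    """Centred moving average with symmetric shrinking windows at the edges.

    Interior points average ``span`` neighbours; the first and last
    ``span//2`` points use the largest centred window that fits (1, 3, 5, ...
    samples), so the output has the input's length and a constant input is
    reproduced exactly.
    """
    if span < 1 or span % 2 == 0:
        raise ParameterError(f"span must be an odd integer >= 1, got {span}")
    x = np.asarray(x, dtype=float)
    n = x.size
    if span == 1 or n == 0:
        return x.copy()
    if n < span:
        # every point is an edge point: largest centred window per point
        out = np.empty(n)
        for i in range(n):
            w = min(i, n - 1 - i)
            out[i] = x[i - w : i + w + 1].mean()
        return out
    half = span // 2
    out = np.convolve(x, np.full(span, 1.0 / span), mode="same")
    for i in range(half):
        out[i] = x[: 2 * i + 1].mean()
        out[n - 1 - i] = x[n - 1 - 2 * i :].mean()
    return out


def smooth_trace(trace: PupilTrace, span: int = DEFAULT_SMOOTH_SPAN) -> PupilTrace:
    """Apply :func:`smooth` to a trace's combined channel."""
    if trace.d is None:
        raise DataError("smooth_trace requires the combined channel; run average_eyes")
    out = trace.copy()
    out.d = smooth(trace.d, span)
    return out


def baseline_correct(trace: PupilTrace, mode: str) -> CleanSignal:
    """Reference a gap-free trace to its pre-stimulus mean.

    ``mode='reference'`` computes the mean diameter over the 3 s before
    onset, stores it as ``baseline`` and leaves the series in absolute mm.
    ``mode='subtract_200ms'`` subtracts the mean of the 200 ms before onset
    from every sample (and stores that mean).
    """
    if mode not in BASELINE_WINDOWS:
        raise ParameterError(
            f"unknown baseline mode {mode!r}; expected one of {sorted(BASELINE_WINDOWS)}"
        )
    if trace.d is None or np.any(~np.isfinite(trace.d)):
        raise DataError("baseline_correct requires a gap-free combined channel")
    window = BASELINE_WINDOWS[mode]
    dt = 1.0 / trace.sampling_rate
    if trace.t[0] > -window + dt / 2:
        raise DataError(
            f"insufficient pre-stimulus data: need {window} s before onset, "
            f"trace starts at t={trace.t[0]:.3f} s"
        )
    pre = (trace.t >= -window) & (trace.t < 0)
    if not pre.any():
        raise DataError("no samples in the pre-stimulus baseline window")
    base = float(trace.d[pre].mean())
    d = trace.d - base if mode == "subtract_200ms" else trace.d.copy()
    return CleanSignal(
        subject=trace.subject,
        trial=trace.trial,
        label=trace.label,
        sampling_rate=trace.sampling_rate,
        t=trace.t.copy(),
        d=d,
        baseline=base,
        baseline_mode=mode,
    )


def average_by_valence(signals) -> list[CleanSignal]:
    """Pointwise mean of each subject's signals of the same valence.

    All signals in a (subject, label) group must share a time grid.  Returns
    one signal per group, ordered by (subject, label).
    """
    signals = list(signals)
    if not signals:
        raise DataError("no signals to average")
    groups: dict[tuple[str, str], list[CleanSignal]] = {}
    for s in signals:
        groups.setdefault((s.subject, s.label), []).append(s)
    out = []
    for (subject, label), members in sorted(groups.items()):
        grid = members[0].t
        for m in members[1:]:
            if m.t.shape != grid.shape or not np.allclose(m.t, grid):
                raise DataError(
                    f"signals of (subject={subject}, label={label}) "
                    "are not on a common time grid"
                )
            if m.baseline_mode != members[0].baseline_mode:
                raise DataError("cannot average signals with mixed baseline modes")
        out.append(
            CleanSignal(
                subject=subject,
                label=label,
                sampling_rate=members[0].sampling_rate,
                t=grid.copy(),
                d=np.mean([m.d for m in members], axis=0),
                baseline=float(np.mean([m.baseline for m in members])),
                baseline_mode=members[0].baseline_mode,
            )
        )
    return out
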