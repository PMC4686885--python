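"""Seeded synthetic pupil-trace cohorts with valence-dependent dynamics.

The generator emulates the measured group-level dynamics of emotional
pupillary responses to roughly 6-s auditory (300 Hz recording) or 5-s
verbal (50 Hz) stimuli: dilation onset about 0.25 s after stimulus onset, a
peak near 2.2 s, a higher peak for negative valence (4.76 mm vs 4.66 mm),
and a sustained tail for negative versus a decaying tail for positive
responses.  On top of the noise-free valence template it adds a per-subject
baseline offset, slow "spontaneous fluctuation" noise, per-eye measurement
jitter, Poisson blink artifacts that invalidate both eyes, and extra random
sample dropout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import yaml

from .exceptions import ParameterError
from .io import PupilTrace
from .preprocess import CleanSignal


@dataclass
class SimConfig:
    """Cohort-generator parameters.

    Dynamics defaults encode the sound-protocol group curves (onset latency
    0.25 s, peak at 2.2 s, peaks 4.76/4.66 mm, sustained negative tail);
    variability defaults (baseline_sd, noise_sd, eye_jitter_sd) are stated
    modelling assumptions, since group-level reports carry no trial-level
    noise figures.
    """

    n_subjects: int = 30
    trials_per_valence: int = 10
    sampling_rate: float = 300.0          # Hz (300 sound protocol, 50 words)
    stimulus_duration: float = 6.0        # s of analyzed post-onset signal
    pre_duration: float = 3.0             # s of pre-stimulus recording
    baseline_mean: float = 4.3            # mm, population pre-stimulus diameter
    baseline_sd: float = 0.3              # mm, between-subject offset SD
    trial_drift_sd: float = 0.1           # mm, trial-to-trial baseline drift SD
    onset_latency: float = 0.25           # s, dilation start after onset
    peak_time: float = 2.2                # s, time of peak dilation
    peak_negative: float = 4.76           # mm, negative-valence peak
    peak_positive: float = 4.66           # mm, positive-valence peak
    sustain_fraction_negative: float = 0.85   # rise fraction retained at T_end
    decay_rate_positive: float = 0.45     # 1/s, exponential tail decay
    noise_sd: float = 0.08                # mm, slow fluctuation SD per trial
    noise_tau: float = 0.3                # s, fluctuation correlation time
    eye_jitter_sd: float = 0.02           # mm, white per-eye measurement noise
    blink_rate: float = 0.15              # blinks per second
    blink_duration: float = 0.15          # s masked per blink
    missing_fraction: float = 0.02        # extra random sample dropout
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "sampling_rate stimulus_duration pre_duration baseline_mean "
            "onset_latency peak_time"
        ).split()
        for name in positive:
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        for name in (
            "baseline_sd trial_drift_sd noise_sd noise_tau eye_jitter_sd "
            "blink_rate blink_duration missing_fraction"
        ).split():
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")
        if min(self.peak_negative, self.peak_positive) <= self.baseline_mean:
            raise ParameterError("valence peaks must exceed baseline_mean")
        if not 0 < self.sustain_fraction_negative <= 1:
            raise ParameterError("sustain_fraction_negative must be in (0, 1]")
        if self.decay_rate_positive <= 0:
            raise ParameterError("decay_rate_positive must be positive")
        if not self.onset_latency < self.peak_time < self.stimulus_duration:
            raise ParameterError("need onset_latency < peak_time < stimulus_duration")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)


def null_dynamics(cfg: SimConfig) -> SimConfig:
    """A copy of ``cfg`` in which both valences share identical dynamics.

    The positive peak is set to the negative one and the positive tail decay
    is matched to the negative plateau, so the two class templates coincide
    and any residual classification accuracy reflects chance alone.
    """
    lam = -np.log(cfg.sustain_fraction_negative) / (
        cfg.stimulus_duration - cfg.peak_time
    )
    return cfg.replace(peak_positive=cfg.peak_negative, decay_rate_positive=float(lam))


def time_grid(cfg: SimConfig) -> np.ndarray:
    """Uniform grid covering [-pre_duration, stimulus_duration] at the sampling rate."""
    n = int(round((cfg.pre_duration + cfg.stimulus_duration) * cfg.sampling_rate))
    return np.arange(n + 1) / cfg.sampling_rate - cfg.pre_duration


def response_template(valence: str, cfg: SimConfig) -> CleanSignal:
    """Noise-free diameter template for one valence on the config's grid.

    Flat baseline until ``onset_latency``, raised-cosine rise to the
    valence's peak at ``peak_time``, then an exponential tail: the negative
    tail relaxes so that ``sustain_fraction_negative`` of the rise remains
    at the end of the stimulus, the positive tail decays at
    ``decay_rate_positive``.  The template maximum equals the configured
    peak exactly.
    """
    if valence not in ("positive", "negative"):
        raise ParameterError(f"valence must be positive or negative, got {valence!r}")
    t = time_grid(cfg)
    peak = cfg.peak_negative if valence == "negative" else cfg.peak_positive
    rise = peak - cfg.baseline_mean
    if valence == "negative":
        rate = -np.log(cfg.sustain_fraction_negative) / (
            cfg.stimulus_duration - cfg.peak_time
        )
    else:
        rate = cfg.decay_rate_positive
    d = np.full(t.size, cfg.baseline_mean)
    rising = (t >= cfg.onset_latency) & (t <= cfg.peak_time)
    phase = (t[rising] - cfg.onset_latency) / (cfg.peak_time - cfg.onset_latency)
    d[rising] += rise * 0.5 * (1 - np.cos(np.pi * phase))
    tail = t > cfg.peak_time
    d[tail] += rise * np.exp(-rate * (t[tail] - cfg.peak_time))
    return CleanSignal(
        subject="template",
        label=valence,
        sampling_rate=cfg.sampling_rate,
        t=t,
        d=d,
        baseline=cfg.baseline_mean,
        baseline_mode="reference",
    )


def _slow_noise(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Band-limited fluctuation: white noise convolved with a Hann kernel.

    Pupil traces drift on a sub-second timescale rather than sample to
    sample; the kernel width is ``noise_tau`` seconds and the output is
    scaled to a per-sample SD of ``noise_sd``.
    """
    if cfg.noise_sd == 0:
        return np.zeros(n)
    width = max(int(round(cfg.noise_tau * cfg.sampling_rate)), 1)
    white = rng.normal(0.0, 1.0, n + width)
    if width == 1:
        return cfg.noise_sd * white[:n]
    kernel = np.hanning(width + 2)[1:-1]
    kernel /= np.sqrt(np.sum(kernel**2))  # unit output variance
    smoothed = np.convolve(white, kernel, mode="same")[:n]
    return cfg.noise_sd * smoothed


def simulate_trial(
    valence: str,
    subject_offset: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    subject: str = "s01",
    trial: str = "t01",
) -> PupilTrace:
    """One synthetic trial: template + offset + fluctuations + artifacts.

    ``subject_offset`` shifts the whole trace (between-subject diameter
    differences); on top of it each trial draws its own baseline-drift
    offset (SD ``trial_drift_sd``), modelling the slow wandering of resting
    diameter over a session.  Blinks arrive as a Poisson process at
    ``blink_rate`` and mask ``blink_duration`` seconds of both eyes; a
    further ``missing_fraction`` of samples is dropped at random.
    """
    template = response_template(valence, cfg)
    t = template.t
    n = t.size
    drift = rng.normal(0.0, cfg.trial_drift_sd) if cfg.trial_drift_sd else 0.0
    d = template.d + subject_offset + drift + _slow_noise(n, cfg, rng)
    left = d + (rng.normal(0.0, cfg.eye_jitter_sd, n) if cfg.eye_jitter_sd else 0.0)
    right = d + (rng.normal(0.0, cfg.eye_jitter_sd, n) if cfg.eye_jitter_sd else 0.0)
    valid = np.ones(n, dtype=bool)

    total = cfg.pre_duration + cfg.stimulus_duration
    n_blinks = rng.poisson(cfg.blink_rate * total)
    starts = rng.uniform(t[0], t[-1], n_blinks)
    for start in starts:
        valid &= ~((t >= start) & (t < start + cfg.blink_duration))
    if cfg.missing_fraction > 0:
        valid &= rng.random(n) >= cfg.missing_fraction

    left = np.where(valid, left, np.nan)
    right = np.where(valid, right, np.nan)
    return PupilTrace(
        subject=subject,
        trial=trial,
        label=valence,
        sampling_rate=cfg.sampling_rate,
        stimulus_duration=cfg.stimulus_duration,
        t=t,
        pd_left=left,
        pd_right=right,
        valid_left=valid.copy(),
        valid_right=valid.copy(),
    )


def simulate_cohort(cfg: SimConfig) -> list[PupilTrace]:
    """A full labeled cohort: n_subjects x 2 valences x trials_per_valence.

    Subjects get independent baseline offsets (SD ``baseline_sd``); the
    whole collection is deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    offsets = rng.normal(0.0, cfg.baseline_sd, cfg.n_subjects)
    traces = []
    for i in range(cfg.n_subjects):
        subject = f"s{i + 1:02d}"
        for valence in ("negative", "positive"):
            for j in range(cfg.trials_per_valence):
                traces.append(
                    simulate_trial(
                        valence,
                        float(offsets[i]),
                        cfg,
                        rng,
                        subject=subject,
                        trial=f"{valence[:3]}{j + 1:02d}",
                    )
                )
    return traces
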