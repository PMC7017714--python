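"""Synthetic peri-event signal generator.

Emulates subject-averaged fiber-photometry recordings: each *line* (a
single trial-like trace) is a zero baseline plus low-pass-filtered white
Gaussian noise, optionally carrying a 1-s parabolic transient whose
magnitude is a half-normal draw (|z|, z standard normal). *Subjects* are
means of 1-31 lines. Two conditions are generated:

- ``ert``  — every line carries a transient starting at the halfway point
  of the window (an event-related transient, ERT);
- ``null`` — each line has a 50% chance of carrying a transient at a
  uniform-random position (an event-unrelated transient), else pure noise.
  Unrelated transients are sign-symmetric (half-normal magnitude with a
  random sign), so the null ensemble stays zero-mean: event-unrelated
  fluctuations have no preferred direction relative to the event, and a
  directionally biased null would make the family-wise Type I rate of
  any interval tested against 0 grow without bound in the sample size.

All outputs are pure functions of the parameters and the RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .core import Trace, TraceMatrix

__all__ = [
    "GeneratorParams",
    "sample_transient_magnitude",
    "parabolic_transient",
    "lowpass_filter",
    "generate_noise_line",
    "generate_line",
    "generate_subject",
    "generate_populations",
    "transient_support",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic line/subject generative model.

    Defaults describe a 10-s window sampled at 10 Hz with noise of
    variance 0.1 (i.e. -10 dB relative to unit power) low-pass filtered
    at 2 Hz, and 1-s transients with half-normal magnitudes.
    """

    n_points: int = 100
    fs: float = 10.0
    noise_power: float = 0.1
    lowpass_hz: float = 2.0
    transient_duration: float = 1.0
    null_transient_prob: float = 0.5
    lines_per_subject_range: tuple[int, int] = (1, 31)
    population_lines: int = 10_000
    population_subjects: int = 1_000
    magnitude_scale: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not 0 < self.lowpass_hz < self.fs / 2:
            raise ValueError("lowpass_hz must lie in (0, fs/2)")
        if self.transient_duration * self.fs < 2:
            raise ValueError("transient_duration * fs must be >= 2")
        if not 0 <= self.null_transient_prob <= 1:
            raise ValueError("null_transient_prob must be in [0, 1]")
        lo, hi = self.lines_per_subject_range
        if lo < 1 or hi < lo:
            raise ValueError("lines_per_subject_range must be positive and ordered")
        if self.noise_power < 0:
            raise ValueError("noise_power must be >= 0")
        if self.magnitude_scale < 0:
            raise ValueError("magnitude_scale must be >= 0")
        if self.population_lines < 1 or self.population_subjects < 1:
            raise ValueError("population sizes must be >= 1")

    @property
    def transient_samples(self) -> int:
        """Length of the transient in samples."""
        return int(round(self.transient_duration * self.fs))

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


def transient_support(params: GeneratorParams) -> tuple[int, int]:
    """Half-open sample index range [start, stop) of the event-locked transient.

    The ERT starts at the halfway point of the window: index
    ``n_points // 2`` (samples 50-59 at the defaults).
    """
    start = params.n_points // 2
    return start, start + params.transient_samples


def sample_transient_magnitude(
    rng: np.random.Generator, scale: float = 1.0
) -> float:
    """Draw a transient magnitude from the half-normal distribution.

    Returns ``scale * |z|`` with z standard normal ("positive tail of the
    z distribution"); always >= 0, expectation ``scale * sqrt(2/pi)``.
    """
    return scale * abs(rng.standard_normal())


def parabolic_transient(duration: float, fs: float, magnitude: float) -> np.ndarray:
    """Discrete parabolic transient of the given duration and peak magnitude.

    The parabola m*(1 - (2t/T - 1)^2) is sampled at the midpoints of the
    k = round(duration*fs) sample intervals covering the duration, so the
    vector is symmetric under reversal and every sample is strictly
    positive (the edges carry the parabola's small near-zero values), and
    is rescaled so the sampled maximum equals ``magnitude`` exactly.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    k = int(round(duration * fs))
    if k < 2:
        raise ValueError("duration * fs must be >= 2 samples")
    x = (2 * np.arange(k) + 1) / k - 1  # interval midpoints of [-1, 1]
    shape = 1.0 - x * x
    return magnitude * shape / shape.max()


def lowpass_filter(x: np.ndarray, fs: float, cutoff: float, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) 2nd-order Butterworth low-pass filter."""
    sos = _signal.butter(2, cutoff, btype="low", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x, axis=axis)


def generate_noise_line(params: GeneratorParams, rng: np.random.Generator) -> Trace:
    """One noise-only line: filtered white Gaussian noise on a zero baseline."""
    return Trace(_noise_lines(params, rng, 1)[0], params.fs)


def _noise_lines(
    params: GeneratorParams, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Matrix of n noise lines (vectorized; one filtfilt over the batch)."""
    if params.noise_power == 0:
        return np.zeros((n, params.n_points))
    white = rng.normal(0.0, math.sqrt(params.noise_power), (n, params.n_points))
    return lowpass_filter(white, params.fs, params.lowpass_hz, axis=-1)


def generate_line(
    condition: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    magnitude: float | None = None,
) -> Trace:
    """One line of the given condition ("ert" or "null").

    ``ert`` lines carry a transient starting at the halfway index;
    ``null`` lines carry one with probability ``null_transient_prob`` at a
    uniform-random start such that it fits wholly inside the window.
    ``magnitude`` overrides the half-normal draw (used for noise-free
    checks and calibration).
    """
    values = _noise_lines(params, rng, 1)[0]
    _maybe_insert_transient(values, condition, params, rng, magnitude)
    return Trace(values, params.fs)


def _maybe_insert_transient(
    values: np.ndarray,
    condition: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    magnitude: float | None = None,
) -> None:
    k = params.transient_samples
    sign = 1.0
    if condition == "ert":
        start = params.n_points // 2
    elif condition == "null":
        if rng.random() >= params.null_transient_prob:
            return
        start = int(rng.integers(0, params.n_points - k + 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
    else:
        raise ValueError(f"unknown condition {condition!r}; expected 'ert' or 'null'")
    if start + k > params.n_points:
        raise ValueError("transient does not fit inside the window")
    if magnitude is None:
        m = sign * sample_transient_magnitude(rng, params.magnitude_scale)
    else:
        m = magnitude  # caller-fixed, used as given (signed)
    values[start : start + k] += parabolic_transient(
        params.transient_duration, params.fs, abs(m)
    ) * np.sign(m)


def generate_subject(
    condition: str,
    params: GeneratorParams,
    rng: np.random.Generator,
    n_lines: int | None = None,
) -> Trace:
    """One subject trace: the mean of k freshly generated lines.

    k is uniform on ``lines_per_subject_range`` unless ``n_lines`` is given.
    """
    lo, hi = params.lines_per_subject_range
    k = int(rng.integers(lo, hi + 1)) if n_lines is None else int(n_lines)
    if k < 1:
        raise ValueError("n_lines must be >= 1")
    lines = np.stack(
        [generate_line(condition, params, rng).values for _ in range(k)]
    )
    return Trace(lines.mean(axis=0), params.fs)


def generate_populations(
    params: GeneratorParams, rng: np.random.Generator | None = None
) -> tuple[TraceMatrix, TraceMatrix]:
    """Generate the (null, ert) subject populations.

    For each condition, ``population_lines`` lines are generated, then
    each of ``population_subjects`` subjects is the mean of k lines
    (k uniform on ``lines_per_subject_range``) sampled without replacement
    from that condition's line pool. Fully reproducible from
    ``params.seed`` when no rng is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_start = -params.n_points / (2 * params.fs)
    out = []
    for condition in ("null", "ert"):
        lines = _noise_lines(params, rng, params.population_lines)
        for row in lines:
            _maybe_insert_transient(row, condition, params, rng)
        lo, hi = params.lines_per_subject_range
        ks = rng.integers(lo, hi + 1, size=params.population_subjects)
        subjects = np.empty((params.population_subjects, params.n_points))
        for i, k in enumerate(ks):
            picks = rng.choice(params.population_lines, size=int(k), replace=False)
            subjects[i] = lines[picks].mean(axis=0)
        out.append(
            TraceMatrix(subjects, fs=params.fs, condition=condition, t_start=t_start)
        )
    return out[0], out[1]
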