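"""Consecutive-significance thresholds.

Converts per-comparison significance masks into transient calls by
demanding a minimum run of consecutive significant samples. Random noise
produces brief, unaligned blips of significance; true event-related
transients stay significant for an extended, aligned period — so a run
threshold pegged to the low-pass filter window removes most family-wise
Type I errors at little cost in power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .waveform_ci import SignificanceMask

__all__ = ["ThresholdSpec", "threshold_length", "apply_consecutive_threshold"]


@dataclass(frozen=True)
class ThresholdSpec:
    """A consecutive threshold, as a fraction of the low-pass window.

    ``fraction`` 0 means no thresholding; 0.5 half the low-pass window;
    1 the full window. ``samples`` overrides the fraction with an explicit
    run length.
    """

    fraction: float = 1.0
    fs: float = 10.0
    lowpass_hz: float = 2.0
    samples: int | None = None

    def resolve(self) -> int:
        k = (
            self.samples
            if self.samples is not None
            else threshold_length(self.fs, self.lowpass_hz, self.fraction)
        )
        if k < 1:
            raise ValueError("resolved threshold must be >= 1 sample")
        return k


def threshold_length(fs: float, lowpass_hz: float, fraction: float) -> int:
    """Run length in samples for a fraction of the low-pass window.

    The low-pass window is 1/lowpass_hz seconds (0.5 s at 2 Hz), so the
    length is ceil(fraction * fs / lowpass_hz), rounded up: at 10 Hz / 2 Hz
    the half threshold is 3 samples and the full threshold 5. Fraction 0
    means no filtering and resolves to 1 (every flagged point is kept).
    """
    if fs <= 0 or lowpass_hz <= 0:
        raise ValueError("fs and lowpass_hz must be positive")
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return 1
    # tolerate float representation of exact integer products
    return int(math.ceil(fraction * fs / lowpass_hz - 1e-9))


def _run_filter(flags: np.ndarray, k: int) -> np.ndarray:
    """Keep flags belonging to a maximal run of True with length >= k."""
    flags = np.asarray(flags, dtype=bool)
    if k == 1 or flags.size == 0:
        return flags.copy()
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    out = np.zeros_like(flags)
    for s, e in zip(starts, ends):
        if e - s >= k:
            out[s:e] = True
    return out


def apply_consecutive_threshold(
    mask: SignificanceMask, k: int, signs: np.ndarray | None = None
) -> SignificanceMask:
    """Zero out every run of consecutive significant samples shorter than k.

    Runs are maximal stretches of True flags regardless of effect
    direction; a run that crosses from significantly-above to
    significantly-below the null without a gap counts as one run. Pass
    ``signs`` (the sign of center - null per timepoint) to enforce the
    stricter mode where a run must also be direction-consistent. Runs
    touching the window edge count with their in-window length.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    flags = mask.flags
    if signs is not None:
        signs = np.sign(np.asarray(signs, dtype=float))
        if signs.size != flags.size:
            raise ValueError("signs must match the mask length")
        out = np.zeros_like(flags)
        for s in (-1.0, 1.0):
            out |= _run_filter(flags & (signs == s), k)
    else:
        out = _run_filter(flags, k)
    return SignificanceMask(out, alpha=mask.alpha, consec_threshold=k)
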