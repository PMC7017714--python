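"""Pointwise confidence intervals across the peri-event waveform.

Implements the parametric t interval (mean +/- SEM * t_crit), the
percentile bootstrap interval with the n/(n-1) expansion that counters
its small-sample narrowness bias, their two-sample counterparts, and the
conversion of an interval band into a per-timepoint significance mask
(significant wherever the interval excludes the null value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import TraceMatrix

__all__ = [
    "WaveformCI",
    "SignificanceMask",
    "t_interval",
    "bootstrap_interval",
    "two_sample_t_interval",
    "two_sample_bootstrap_interval",
    "significance_from_ci",
    "summarize_window",
]


@dataclass(frozen=True)
class WaveformCI:
    """Pointwise confidence band over a waveform.

    ``center`` is the sample mean (one-sample) or mean difference
    (two-sample); ``n`` is the sample size or (n_a, n_b).
    """

    lower: np.ndarray
    upper: np.ndarray
    center: np.ndarray
    level: float
    method: str
    n: int | tuple[int, int]

    def __post_init__(self) -> None:
        if not (len(self.lower) == len(self.upper) == len(self.center)):
            raise ValueError("lower, upper and center must have equal length")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0, 1)")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower


@dataclass(frozen=True)
class SignificanceMask:
    """Boolean per-timepoint significance flags.

    ``consec_threshold`` records the consecutive-run length (in samples)
    already enforced on the flags; 0 means none.
    """

    flags: np.ndarray
    alpha: float
    consec_threshold: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "flags", np.asarray(self.flags, dtype=bool))

    def __len__(self) -> int:
        return self.flags.size

    @property
    def any_significant(self) -> bool:
        return bool(self.flags.any())


def _check_matrix(data: TraceMatrix, min_n: int = 2) -> np.ndarray:
    x = data.values
    if x.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} traces, got {x.shape[0]}")
    return x


def t_interval(data: TraceMatrix, level: float = 0.95) -> WaveformCI:
    """Pointwise t interval: mean +/- SEM * t_crit, df = n - 1."""
    x = _check_matrix(data)
    n = x.shape[0]
    mean = x.mean(axis=0)
    sem = x.std(axis=0, ddof=1) / np.sqrt(n)
    t_crit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    half = sem * t_crit
    return WaveformCI(mean - half, mean + half, mean, level, "t", n)


def _percentile_bounds(
    boot: np.ndarray, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bounds of a bootstrap matrix (replicates x timepoints).

    Linear interpolation between order statistics (95%: 2.5/97.5,
    99%: 0.5/99.5 percentiles).
    """
    alpha = 1 - level
    lo, hi = np.percentile(
        boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0, method="linear"
    )
    return lo, hi


def bootstrap_interval(
    data: TraceMatrix,
    level: float = 0.95,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    expand: bool = True,
) -> WaveformCI:
    """Pointwise percentile bootstrap interval on the mean waveform.

    Whole traces (rows) are resampled with replacement ``n_boot`` times;
    bounds are percentiles of the bootstrap means per timepoint. With
    ``expand`` the bounds are moved away from the sample mean by the
    factor n/(n-1), countering the percentile interval's small-sample
    narrowness bias:  bound' = mean + (bound - mean) * n/(n-1).
    """
    x = _check_matrix(data)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    n = x.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = x[idx].mean(axis=1)
    lower, upper = _percentile_bounds(boot_means, level)
    mean = x.mean(axis=0)
    if expand:
        factor = n / (n - 1)
        lower = mean + (lower - mean) * factor
        upper = mean + (upper - mean) * factor
    return WaveformCI(lower, upper, mean, level, "bootstrap", n)


def two_sample_t_interval(
    a: TraceMatrix, b: TraceMatrix, level: float = 0.95
) -> WaveformCI:
    """Pointwise Welch t interval on mean(a) - mean(b)."""
    xa, xb = _check_matrix(a), _check_matrix(b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"trace length mismatch: {xa.shape[1]} vs {xb.shape[1]}"
        )
    na, nb = xa.shape[0], xb.shape[0]
    va = xa.var(axis=0, ddof=1) / na
    vb = xb.var(axis=0, ddof=1) / nb
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    se = np.sqrt(va + vb)
    # Welch-Satterthwaite df; degenerate (zero-variance) points get the
    # pooled df so the critical value stays finite (half-width is 0 there).
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    df = np.where(np.isfinite(df), df, na + nb - 2)
    t_crit = stats.t.ppf(0.5 + level / 2, df=df)
    half = se * t_crit
    return WaveformCI(diff - half, diff + half, diff, level, "t", (na, nb))


def two_sample_bootstrap_interval(
    a: TraceMatrix,
    b: TraceMatrix,
    level: float = 0.95,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> WaveformCI:
    """Percentile interval of the bootstrap difference distribution.

    Each replicate resamples a and b independently (whole rows, with
    replacement) and records mean(a*) - mean(b*).
    """
    xa, xb = _check_matrix(a), _check_matrix(b)
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(
            f"trace length mismatch: {xa.shape[1]} vs {xb.shape[1]}"
        )
    if rng is None:
        rng = np.random.default_rng()
    na, nb = xa.shape[0], xb.shape[0]
    ia = rng.integers(0, na, size=(n_boot, na))
    ib = rng.integers(0, nb, size=(n_boot, nb))
    boot_diff = xa[ia].mean(axis=1) - xb[ib].mean(axis=1)
    lower, upper = _percentile_bounds(boot_diff, level)
    diff = xa.mean(axis=0) - xb.mean(axis=0)
    return WaveformCI(lower, upper, diff, level, "bootstrap", (na, nb))


def significance_from_ci(ci: WaveformCI, null_value: float = 0.0) -> SignificanceMask:
    """Flag timepoints whose interval excludes the null value.

    Endpoints are closed: an interval touching the null exactly contains
    it and is not significant (conservative tie-break).
    """
    flags = (ci.upper < null_value) | (ci.lower > null_value)
    return SignificanceMask(flags, alpha=1 - ci.level)


def summarize_window(
    data: TraceMatrix, window: tuple[float, float]
) -> dict[str, np.ndarray]:
    """Per-row trapezoidal AUC (dF*s) and peak dF over a time window.

    ``window`` is (start, stop) in seconds on the matrix's time axis,
    half-open [start, stop). Convenience for comparing waveform analyses
    with classical summary statistics.
    """
    start, stop = window
    t = data.times
    sel = (t >= start) & (t < stop)
    if sel.sum() == 0:
        raise ValueError(f"window {window} selects no samples")
    seg = data.values[:, sel]
    return {
        "auc": np.trapezoid(seg, dx=1.0 / data.fs, axis=1),
        "peak": seg.max(axis=1),
    }
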