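"""Core containers for peri-event waveform data.

A :class:`Trace` is a single peri-event dF vector with its sampling rate;
a :class:`TraceMatrix` is an aligned stack of such vectors (one row per
subject or trial), the common input to every analysis in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "TraceMatrix"]

#: Allowed condition labels for generated data.
CONDITIONS = ("null", "ert", "baseline")


@dataclass(frozen=True)
class Trace:
    """One peri-event dF vector sampled at a fixed rate.

    Parameters
    ----------
    values : ndarray
        dF values, finite, length >= 1.
    fs : float
        Sampling rate in Hz, > 0.
    """

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("Trace values must be a non-empty 1-D vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("Trace values must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Window length in seconds (n / fs)."""
        return self.values.size / self.fs


@dataclass
class TraceMatrix:
    """Rectangular stack of equally sampled traces (rows = subjects/trials).

    Attributes
    ----------
    values : ndarray, shape (n_traces, n_points)
    fs : float
        Common sampling rate in Hz.
    condition : str or None
        Optional label: "null", "ert" or "baseline".
    t_start : float
        Time of the first sample in seconds (peri-event convention:
        negative values are pre-event).
    """

    values: np.ndarray
    fs: float
    condition: str | None = None
    t_start: float = 0.0
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("TraceMatrix requires a non-empty 2-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("TraceMatrix values must be finite")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.subject_ids and len(self.subject_ids) != values.shape[0]:
            raise ValueError("subject_ids length must match the number of rows")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(values.shape[0])]
        self.values = values

    @classmethod
    def from_traces(
        cls, traces: list[Trace], condition: str | None = None, t_start: float = 0.0
    ) -> "TraceMatrix":
        if not traces:
            raise ValueError("need at least one trace")
        fs = traces[0].fs
        n = len(traces[0])
        for i, tr in enumerate(traces):
            if tr.fs != fs:
                raise ValueError(f"trace {i} has fs {tr.fs}, expected {fs}")
            if len(tr) != n:
                raise ValueError(f"trace {i} has length {len(tr)}, expected {n}")
        return cls(
            np.stack([tr.values for tr in traces]),
            fs=fs,
            condition=condition,
            t_start=t_start,
        )

    @property
    def n_traces(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t_start + np.arange(self.n_points) / self.fs

    def row(self, i: int) -> Trace:
        return Trace(self.values[i], self.fs)

    def subset(self, indices) -> "TraceMatrix":
        """New matrix restricted to the given row indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return TraceMatrix(
            self.values[idx],
            fs=self.fs,
            condition=self.condition,
            t_start=self.t_start,
            subject_ids=[self.subject_ids[i] for i in idx],
        )
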