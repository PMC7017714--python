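"""Readers, writers and run manifests.

TraceMatrix CSV layout: first column is the subject/trial id, the header
row carries the sample times in seconds, one row per trace. The sampling
rate is inferred from the (uniform) time grid on read. Every CLI run also
emits a JSON manifest (version, config echo, seed, file digests) from
which the run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TraceMatrix
from .waveform_ci import SignificanceMask, WaveformCI

__all__ = [
    "read_trace_matrix",
    "write_trace_matrix",
    "significant_runs",
    "write_analysis_report",
    "RunManifest",
]

_REL_TOL = 1e-6  # uniformity tolerance on the time grid


def write_trace_matrix(matrix: TraceMatrix, path: str | Path) -> Path:
    """Write a TraceMatrix as CSV (subject id column + time-stamped header)."""
    path = Path(path)
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.subject_ids, name="subject"),
        columns=[format(t, ".10g") for t in matrix.times],
    )
    df.to_csv(path, float_format="%.17g")
    return path


def read_trace_matrix(path: str | Path, condition: str | None = None) -> TraceMatrix:
    """Read a TraceMatrix CSV, inferring fs from the header time grid."""
    path = Path(path)
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ValueError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 timepoint columns to infer fs")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ValueError(f"{path}: header must be sample times in seconds") from exc
    values = df.to_numpy(dtype=float)
    for i in range(values.shape[0]):
        if not np.all(np.isfinite(values[i])):
            raise ValueError(
                f"{path}: row {df.index[i]!r} has missing or non-numeric cells"
            )
    dt = np.diff(times)
    mean_dt = dt.mean()
    if mean_dt <= 0 or np.any(np.abs(dt - mean_dt) > _REL_TOL * abs(mean_dt)):
        raise ValueError(f"{path}: time grid is not uniform")
    return TraceMatrix(
        values,
        fs=1.0 / mean_dt,
        condition=condition,
        t_start=times[0],
        subject_ids=[str(s) for s in df.index],
    )


def significant_runs(
    flags: np.ndarray,
    fs: float,
    t_start: float = 0.0,
    center: np.ndarray | None = None,
) -> list[dict]:
    """Maximal runs of significant samples as half-open [start, end) seconds.

    Each run reports its direction (sign of the center waveform at the
    run's peak) and the peak center value when a center is supplied.
    """
    flags = np.asarray(flags, dtype=bool)
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = []
    for s, e in zip(starts, ends):
        run = {
            "start_s": t_start + s / fs,
            "end_s": t_start + e / fs,
            "n_samples": int(e - s),
        }
        if center is not None:
            seg = np.asarray(center, dtype=float)[s:e]
            peak = seg[np.argmax(np.abs(seg))]
            run["direction"] = "above" if peak > 0 else "below"
            run["peak_center"] = float(peak)
        runs.append(run)
    return runs


def write_analysis_report(
    out_prefix: str | Path,
    times: np.ndarray,
    mask_raw: SignificanceMask,
    mask_thresholded: SignificanceMask,
    ci: WaveformCI | None = None,
    p_values: np.ndarray | None = None,
) -> tuple[Path, Path]:
    """Write the per-timepoint CSV and JSON run summary for one analysis.

    Returns (csv_path, json_path). The JSON lists the significant runs of
    the thresholded mask in seconds.
    """
    out_prefix = Path(out_prefix)
    n = len(mask_raw.flags)
    if len(times) != n or len(mask_thresholded.flags) != n:
        raise ValueError("times and masks must have equal length")
    cols: dict[str, np.ndarray] = {"time_s": np.asarray(times, dtype=float)}
    center = None
    if ci is not None:
        if len(ci.center) != n:
            raise ValueError("interval length does not match the masks")
        center = ci.center
        cols.update(center=ci.center, lower=ci.lower, upper=ci.upper)
    if p_values is not None:
        if len(p_values) != n:
            raise ValueError("p-values length does not match the masks")
        cols["p"] = np.asarray(p_values, dtype=float)
    cols["flag_raw"] = mask_raw.flags.astype(int)
    cols["flag_thresholded"] = mask_thresholded.flags.astype(int)

    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")

    fs = 1.0 / float(np.mean(np.diff(times))) if n > 1 else 1.0
    summary = {
        "alpha": round(mask_raw.alpha, 10),
        "consec_threshold_samples": mask_thresholded.consec_threshold,
        "n_timepoints": n,
        "significant_runs": significant_runs(
            mask_thresholded.flags, fs, t_start=float(times[0]), center=center
        ),
    }
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    return csv_path, json_path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to reproduce it."""

    command: str
    config: dict
    seed: int | None
    version: str = ""
    timestamp: str = ""
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[str(p)] = _sha256(p)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path
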