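"""Monte Carlo error-rate study of waveform ERT detectors.

Repeatedly samples n subjects from the synthetic null and ERT subject
populations, analyzes each sample with the chosen detector (t interval,
expanded percentile bootstrap interval, or permutation test against a
fresh null-population baseline), applies consecutive thresholds, and
summarizes:

- FWER: proportion of null-condition simulations with any significant
  flag anywhere in the peri-event window;
- mean correct-reject rate: mean fraction of the transient-support
  samples flagged in ERT-condition simulations;
- miss rate: proportion of ERT-condition simulations with no flag at all
  inside the transient support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .core import TraceMatrix
from .permutation import permutation_test, significance_from_p
from .synthgen import GeneratorParams, generate_populations, transient_support
from .thresholding import apply_consecutive_threshold, threshold_length
from .waveform_ci import (
    SignificanceMask,
    bootstrap_interval,
    significance_from_ci,
    t_interval,
)

__all__ = ["StudyConfig", "TrialResult", "MonteCarloSummary", "run_trial", "run_study"]

METHODS = ("tci", "bci", "perm")


@dataclass(frozen=True)
class StudyConfig:
    """Grid and sizes of a Monte Carlo study."""

    sample_sizes: tuple[int, ...] = (5, 10, 20, 40)
    levels: tuple[float, ...] = (0.95, 0.99)
    threshold_fractions: tuple[float, ...] = (0.0, 0.5, 1.0)
    methods: tuple[str, ...] = METHODS
    n_sims: int = 1000
    n_boot: int = 1000
    max_perm: int = 1000
    #: permutation tail counting; "one" matches the study convention of
    #: counting permutations whose difference exceeds the observed one
    perm_tail: str = "one"
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if min(self.sample_sizes) < 2:
            raise ValueError("sample sizes must be >= 2")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; expected one of {METHODS}")
        for lv in self.levels:
            if not 0 < lv < 1:
                raise ValueError("levels must be in (0, 1)")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated sample under one analysis cell."""

    condition: str
    method: str
    n: int
    level: float
    threshold_samples: int
    any_false_positive: bool | None = None  # null condition
    ert_fraction_rejected: float | None = None  # ert condition
    detected: bool | None = None  # ert condition


@dataclass
class MonteCarloSummary:
    """Tidy per-cell summary table.

    One row per (method, n, level, threshold_fraction) with columns
    fwer, mean_correct_reject, miss_rate, n_sims.
    """

    table: pd.DataFrame
    config: StudyConfig

    def cell(
        self, method: str, n: int, level: float, threshold_fraction: float
    ) -> pd.Series:
        t = self.table
        sel = (
            (t.method == method)
            & (t.n == n)
            & (t.level == level)
            & (t.threshold_fraction == threshold_fraction)
        )
        if sel.sum() != 1:
            raise KeyError(
                f"no unique cell ({method}, {n}, {level}, {threshold_fraction})"
            )
        return t[sel].iloc[0]


def _sample_indices(
    rng: np.random.Generator, pop_size: int, n: int, need_baseline: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Analysis (and optional disjoint baseline) row draws, no replacement."""
    need = 2 * n if need_baseline else n
    if need > pop_size:
        raise ValueError(f"cannot draw {need} distinct subjects from {pop_size}")
    picks = rng.choice(pop_size, size=need, replace=False)
    return (picks[:n], picks[n:]) if need_baseline else (picks, None)


def _raw_mask(
    sample: TraceMatrix,
    baseline: TraceMatrix | None,
    method: str,
    level: float,
    rng: np.random.Generator,
    n_boot: int,
    max_perm: int,
    perm_tail: str,
) -> SignificanceMask:
    if method == "tci":
        return significance_from_ci(t_interval(sample, level), 0.0)
    if method == "bci":
        ci = bootstrap_interval(sample, level, n_boot=n_boot, rng=rng, expand=True)
        return significance_from_ci(ci, 0.0)
    if method == "perm":
        res = permutation_test(
            sample, baseline, max_perm=max_perm, rng=rng, tail=perm_tail
        )
        return significance_from_p(res, alpha=1 - level)
    raise ValueError(f"unknown method {method!r}")


def _trial_raw_masks(
    null_pop: TraceMatrix,
    ert_pop: TraceMatrix,
    method: str,
    n: int,
    level: float,
    rng: np.random.Generator,
    n_boot: int,
    max_perm: int,
    perm_tail: str = "one",
) -> dict[str, SignificanceMask]:
    """Unthresholded masks for one simulation's null and ERT samples.

    One fresh baseline sample per simulation (permutation only), drawn
    from the null population disjointly from the null analysis sample and
    shared by both comparisons.
    """
    need_baseline = method == "perm"
    null_idx, base_idx = _sample_indices(
        rng, null_pop.n_traces, n, need_baseline
    )
    ert_idx = rng.choice(ert_pop.n_traces, size=n, replace=False)
    null_sample = null_pop.subset(null_idx)
    ert_sample = ert_pop.subset(ert_idx)
    baseline = null_pop.subset(base_idx) if need_baseline else None
    return {
        "null": _raw_mask(
            null_sample, baseline, method, level, rng, n_boot, max_perm, perm_tail
        ),
        "ert": _raw_mask(
            ert_sample, baseline, method, level, rng, n_boot, max_perm, perm_tail
        ),
    }


def _score(
    masks: dict[str, SignificanceMask], k: int, support: tuple[int, int]
) -> tuple[bool, float]:
    """(any_false_positive, ert_fraction_rejected) after run-thresholding.

    Flags survive thresholding over the whole window first, then the ERT
    score is the fraction of flagged samples inside the transient support
    (a surviving run straddling the support boundary contributes its
    in-support samples).
    """
    null_flags = apply_consecutive_threshold(masks["null"], k).flags
    ert_flags = apply_consecutive_threshold(masks["ert"], k).flags
    lo, hi = support
    return bool(null_flags.any()), float(ert_flags[lo:hi].mean())


def run_trial(
    null_pop: TraceMatrix,
    ert_pop: TraceMatrix,
    method: str,
    n: int,
    level: float,
    threshold_samples: int,
    rng: np.random.Generator,
    n_boot: int = 1000,
    max_perm: int = 1000,
    perm_tail: str = "one",
    support: tuple[int, int] | None = None,
) -> tuple[TrialResult, TrialResult]:
    """One simulation: a (null-condition, ert-condition) result pair."""
    if support is None:
        # default generator geometry: 1-s transient at the halfway point
        params = GeneratorParams(
            n_points=null_pop.n_points, fs=null_pop.fs
        )
        support = transient_support(params)
    masks = _trial_raw_masks(
        null_pop, ert_pop, method, n, level, rng, n_boot, max_perm, perm_tail
    )
    any_fp, frac = _score(masks, threshold_samples, support)
    common = dict(method=method, n=n, level=level, threshold_samples=threshold_samples)
    return (
        TrialResult(condition="null", any_false_positive=any_fp, **common),
        TrialResult(
            condition="ert",
            ert_fraction_rejected=frac,
            detected=frac > 0,
            **common,
        ),
    )


def run_study(
    config: StudyConfig,
    populations: tuple[TraceMatrix, TraceMatrix] | None = None,
) -> MonteCarloSummary:
    """Run the full (method, n, level) x threshold grid.

    Each (method, n, level) cell runs ``n_sims`` independent simulations;
    all threshold fractions are scored on the same per-simulation raw
    mask (thresholding is deterministic post-processing). Every trial has
    its own RNG stream spawned from the master seed, so cells are
    reproducible independently of execution order.
    """
    master = np.random.SeedSequence(config.seed)
    pop_ss, cells_ss = master.spawn(2)
    if populations is None:
        null_pop, ert_pop = generate_populations(
            config.generator, np.random.default_rng(pop_ss)
        )
    else:
        null_pop, ert_pop = populations
    support = transient_support(config.generator)
    ks = {
        frac: threshold_length(
            config.generator.fs, config.generator.lowpass_hz, frac
        )
        for frac in config.threshold_fractions
    }

    cells = list(product(config.methods, config.sample_sizes, config.levels))
    cell_seeds = cells_ss.spawn(len(cells))
    rows = []
    for (method, n, level), cell_seed in zip(cells, cell_seeds):
        any_fp = {frac: np.zeros(config.n_sims, dtype=bool) for frac in ks}
        fracs = {frac: np.zeros(config.n_sims) for frac in ks}
        for i, trial_seed in enumerate(cell_seed.spawn(config.n_sims)):
            rng = np.random.default_rng(trial_seed)
            masks = _trial_raw_masks(
                null_pop,
                ert_pop,
                method,
                n,
                level,
                rng,
                config.n_boot,
                config.max_perm,
                config.perm_tail,
            )
            for frac, k in ks.items():
                any_fp[frac][i], fracs[frac][i] = _score(masks, k, support)
        for frac in config.threshold_fractions:
            rows.append(
                {
                    "method": method,
                    "n": n,
                    "level": level,
                    "threshold_fraction": frac,
                    "threshold_samples": ks[frac],
                    "fwer": any_fp[frac].mean(),
                    "mean_correct_reject": fracs[frac].mean(),
                    "miss_rate": (fracs[frac] == 0).mean(),
                    "n_sims": config.n_sims,
                }
            )
    return MonteCarloSummary(pd.DataFrame(rows), config)
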