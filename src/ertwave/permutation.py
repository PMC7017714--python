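"""Pointwise two-sample permutation tests across the waveform.

Rows (whole traces) are reassigned between the two groups; the test
statistic at each timepoint is the group mean difference. When the number
of distinct assignments C(n_a + n_b, n_a) does not exceed ``max_perm``
the enumeration is exhaustive (the observed assignment included), giving
exact p-values; otherwise ``max_perm`` random reassignments are drawn and
the observed statistic is added to the permutation set, p = (b+1)/(m+1),
so p can never be 0.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .core import TraceMatrix
from .waveform_ci import SignificanceMask

__all__ = [
    "PermutationResult",
    "permutation_test",
    "min_attainable_p",
    "significance_from_p",
]


@dataclass(frozen=True)
class PermutationResult:
    """Per-timepoint permutation p-values.

    ``exhaustive`` is True when every distinct group assignment was
    enumerated, in which case the p-values are exact.
    """

    p_values: np.ndarray
    n_permutations_used: int
    exhaustive: bool

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        if np.any(p <= 0) or np.any(p > 1):
            raise ValueError("p-values must lie in (0, 1]")
        object.__setattr__(self, "p_values", p)


def permutation_test(
    a: TraceMatrix,
    b: TraceMatrix,
    max_perm: int = 1000,
    rng: np.random.Generator | None = None,
    tail: str = "two",
) -> PermutationResult:
    """Pointwise permutation test of mean(a) vs mean(b).

    Two-sided by default: p at a timepoint is the proportion of
    permutations whose |mean difference| is at least the observed
    |mean difference| (ties count as extreme). ``tail="one"`` counts
    signed differences >= the observed one instead.
    """
    if tail not in ("two", "one"):
        raise ValueError("tail must be 'two' or 'one'")
    xa, xb = a.values, b.values
    na, nb = xa.shape[0], xb.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 traces")
    if xa.shape[1] != xb.shape[1]:
        raise ValueError(f"trace length mismatch: {xa.shape[1]} vs {xb.shape[1]}")
    pooled = np.vstack([xa, xb])
    n_total = na + nb
    observed = xa.mean(axis=0) - xb.mean(axis=0)

    n_comb = math.comb(n_total, na)
    exhaustive = n_comb <= max_perm
    if exhaustive:
        idx_a = np.array(
            list(itertools.combinations(range(n_total), na)), dtype=int
        )
    else:
        if rng is None:
            rng = np.random.default_rng()
        # random group-a index sets via argpartition of random keys
        keys = rng.random((max_perm, n_total))
        idx_a = np.argsort(keys, axis=1)[:, :na]

    # group-a rows determine group b: use the pooled total to avoid a gather
    total = pooled.sum(axis=0)
    sum_a = pooled[idx_a].sum(axis=1)  # (m, T)
    diffs = sum_a / na - (total - sum_a) / nb

    # ties count as extreme; absorb float summation noise so that exactly
    # tied assignments (e.g. mirrored labels) are counted symmetrically
    tol = 1e-9 * (np.abs(pooled).max(axis=0) + 1.0)
    if tail == "two":
        hits = (np.abs(diffs) >= np.abs(observed) - tol).sum(axis=0)
    else:
        hits = (diffs >= observed - tol).sum(axis=0)

    if exhaustive:
        p = hits / n_comb
        used = n_comb
    else:
        p = (hits + 1) / (len(idx_a) + 1)
        used = len(idx_a)
    return PermutationResult(p, used, exhaustive)


def min_attainable_p(n_a: int, n_b: int) -> float:
    """Smallest p-value an exhaustive permutation test can report.

    The granularity of the test is set by the number of distinct group
    assignments: 1 / C(n_a + n_b, n_a), counting only the single most
    extreme assignment (e.g. n_a = n_b = 4 gives 1/70 ~ 0.014). With one
    observation per group no reassignment is informative and the minimum
    is 1.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    if n_a == 1 and n_b == 1:
        return 1.0
    return 1.0 / math.comb(n_a + n_b, n_a)


def significance_from_p(result: PermutationResult, alpha: float) -> SignificanceMask:
    """Flag timepoints with p strictly below alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return SignificanceMask(result.p_values < alpha, alpha=alpha)
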