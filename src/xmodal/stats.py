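"""Resampling statistics: hierarchical bootstrap, permutation tests, Bonferroni.

These utilities are shared by the behavioral, decoding, and geometry modules.
The hierarchical bootstrap resamples with replacement at each level of a
nesting hierarchy (e.g. mice -> sessions -> trials) so that confidence
intervals respect non-independence of nested observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np


@dataclass
class ResampleCI:
    """A point estimate with a resampled 95% confidence interval."""

    estimate: float
    lo: float
    hi: float
    n_iter: int
    levels: tuple[str, ...] = ()
    reference: float | None = None

    @property
    def significant(self) -> bool | None:
        """True when the CI excludes the reference value (if one was set)."""
        if self.reference is None:
            return None
        return not (self.lo <= self.reference <= self.hi)

    def __iter__(self):
        return iter((self.estimate, self.lo, self.hi))


def _resample_nested(data, rng: np.random.Generator, depth: int):
    """Resample a nested list-of-lists with replacement at every level.

    ``depth`` counts the remaining grouping levels; at depth 0 ``data`` is a
    leaf array of observations, resampled with its size preserved.
    """
    if depth == 0:
        arr = np.asarray(data, dtype=float)
        if arr.size == 0:
            return arr
        return arr[rng.integers(0, arr.size, size=arr.size)]
    groups = [g for g in data if _group_size(g, depth - 1) > 0]
    if not groups:
        return []
    picks = rng.integers(0, len(groups), size=len(groups))
    return [_resample_nested(groups[i], rng, depth - 1) for i in picks]


def _has_empty_group(data, depth: int) -> bool:
    if depth == 0:
        return False
    return any(_group_size(g, depth - 1) == 0 for g in data) or any(
        _has_empty_group(g, depth - 1) for g in data)


def _group_size(data, depth: int) -> int:
    if depth == 0:
        return np.asarray(data).size
    return sum(_group_size(g, depth - 1) for g in data)


def _flatten(data, depth: int) -> np.ndarray:
    if depth == 0:
        return np.asarray(data, dtype=float).ravel()
    if not data:
        return np.array([])
    return np.concatenate([_flatten(g, depth - 1) for g in data]) if data else np.array([])


def hierarchical_bootstrap(
    data,
    statistic: Callable[[np.ndarray], float] = np.mean,
    levels: Sequence[str] = ("group", "observation"),
    n_iter: int = 1000,
    seed: int | None = None,
    reference: float | None = None,
) -> ResampleCI:
    """Percentile 95% CI from a nested bootstrap.

    Parameters
    ----------
    data
        Nested lists with ``len(levels) - 1`` grouping levels; the innermost
        elements are 1-d arrays of observations.  For example with
        ``levels=("mice", "sessions", "trials")``, ``data`` is a list (mice)
        of lists (sessions) of arrays (trial observations).
    statistic
        Applied to the pooled (flattened) resampled observations.
    reference
        Optional null value; the result's ``significant`` flag reports
        whether the CI excludes it.
    """
    depth = len(levels) - 1
    if _group_size(data, depth) == 0:
        raise ValueError("no observations at the bottom level")
    if _has_empty_group(data, depth):
        warnings.warn("empty groups skipped during hierarchical resampling")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(_flatten(data, depth)))
    stats = np.empty(n_iter)
    for i in range(n_iter):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resampled = _resample_nested(data, rng, depth)
        stats[i] = statistic(_flatten(resampled, depth))
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return ResampleCI(
        estimate=estimate,
        lo=float(lo),
        hi=float(hi),
        n_iter=n_iter,
        levels=tuple(levels),
        reference=reference,
    )


def bootstrap_ci_of_groups(
    group_values: Sequence[Sequence[float]],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_iter: int = 1000,
    seed: int | None = None,
    reference: float | None = None,
    levels: tuple[str, ...] = ("group", "observation"),
) -> ResampleCI:
    """Two-level convenience wrapper (e.g. sessions -> per-session values)."""
    data = [np.atleast_1d(np.asarray(g, dtype=float)) for g in group_values]
    return hierarchical_bootstrap(
        data, statistic=statistic, levels=levels, n_iter=n_iter, seed=seed,
        reference=reference,
    )


def permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    statistic: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 1000,
    tail: str = "greater",
    seed: int | None = None,
) -> float:
    """Label-permutation p-value with the add-one convention.

    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` for ``tail="greater"``;
    ``tail="two-sided"`` uses ``|null| >= |observed|``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("permutation test requires non-empty groups")
    rng = np.random.default_rng(seed)
    observed = statistic(a, b)
    pooled = np.concatenate([a, b])
    n_a = a.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[i] = statistic(pooled[perm[:n_a]], pooled[perm[n_a:]])
    if tail == "greater":
        exceed = np.sum(null >= observed)
    elif tail == "less":
        exceed = np.sum(null <= observed)
    elif tail == "two-sided":
        exceed = np.sum(np.abs(null) >= abs(observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + exceed) / (n_perm + 1))


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-comparison alpha after correction for ``m`` comparisons."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bonferroni_pvalues(p_values, m: int | None = None) -> np.ndarray:
    """Adjusted p-values ``min(1, m * p)``; ``m`` defaults to ``len(p_values)``."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
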