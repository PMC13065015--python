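"""Validation statistics: ordered trend test and algorithm accuracy.

* Jonckheere-Terpstra test for a monotone trend in serum PFAS concentrations
  across the ordered exposure categories (with midrank tie credit,
  tie-corrected normal approximation, and exact enumeration for tiny
  samples).
* Sensitivity/specificity of a register phenotyping algorithm against a
  gold-standard classification (e.g. primary-care records, or the
  generator's latent labels on synthetic data).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TrendTestResult", "ConfusionTable",
    "jonckheere_terpstra", "confusion_metrics",
]

EXACT_N_MAX = 10


@dataclasses.dataclass
class TrendTestResult:
    statistic: float         # J
    z: float                 # tie-corrected standardized statistic
    p_value: float           # one-sided
    exact: bool
    n: int
    max_statistic: float     # sum over pairs of n_i * n_j


@dataclasses.dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _j_statistic(groups: Sequence[np.ndarray]) -> float:
    """Sum over ordered group pairs of Mann-Whitney counts with tie credit 1/2."""
    j = 0.0
    for a, b in itertools.combinations(groups, 2):
        less = (a[:, None] < b[None, :]).sum()
        ties = (a[:, None] == b[None, :]).sum()
        j += less + 0.5 * ties
    return float(j)


def _tie_corrected_variance(pooled: np.ndarray, sizes: np.ndarray) -> float:
    """Null variance of J under random assignment, corrected for ties."""
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    t = counts.astype(float)
    ni = sizes.astype(float)
    term1 = (
        n * (n - 1) * (2 * n + 5)
        - np.sum(ni * (ni - 1) * (2 * ni + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    term2 = (
        np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(t * (t - 1) * (t - 2))
    ) / (36.0 * n * (n - 1) * (n - 2)) if n > 2 else 0.0
    term3 = (np.sum(ni * (ni - 1)) * np.sum(t * (t - 1))) / (8.0 * n * (n - 1))
    return float(term1 + term2 + term3)


def _exact_pvalue(pooled: np.ndarray, sizes: Sequence[int], j_obs: float) -> float:
    """Enumerate all assignments of the pooled values to the group sizes."""
    idx_all = tuple(range(pooled.size))

    def recurse(remaining: tuple, size_list: Sequence[int]):
        if not size_list:
            yield ()
            return
        k = size_list[0]
        for combo in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in combo)
            for tail in recurse(rest, size_list[1:]):
                yield (combo,) + tail

    count_ge = 0
    total = 0
    tol = 1e-9
    for assignment in recurse(idx_all, list(sizes)):
        groups = [pooled[list(c)] for c in assignment]
        total += 1
        if _j_statistic(groups) >= j_obs - tol:
            count_ge += 1
    return count_ge / total


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    alternative: str = "increasing",
    exact: Optional[bool] = None,
) -> TrendTestResult:
    """Jonckheere-Terpstra test against an ordered (monotone) alternative.

    ``groups`` are samples in increasing order of the grouping category.
    Exact enumeration is used when the total sample size is at most
    ``EXACT_N_MAX`` (or when forced via ``exact=True``); otherwise the
    tie-corrected normal approximation.  All-tied data yield z = 0, p = 1.
    """
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty ordered groups")
    if alternative == "decreasing":
        arrays = [-(a) for a in arrays]

    sizes = np.array([a.size for a in arrays])
    n = int(sizes.sum())
    pooled = np.concatenate(arrays)
    j = _j_statistic(arrays)
    max_j = float(sum(
        sizes[i] * sizes[k] for i, k in itertools.combinations(range(len(arrays)), 2)
    ))

    use_exact = exact if exact is not None else n <= EXACT_N_MAX
    if use_exact:
        p = _exact_pvalue(pooled, sizes.tolist(), j)
        mean_j = max_j / 2.0
        var_j = _tie_corrected_variance(pooled, sizes)
        z = (j - mean_j) / np.sqrt(var_j) if var_j > 0 else 0.0
        return TrendTestResult(j, float(z), float(p), True, n, max_j)

    mean_j = max_j / 2.0
    var_j = _tie_corrected_variance(pooled, sizes)
    if var_j <= 0:
        return TrendTestResult(j, 0.0, 1.0, False, n, max_j)
    z = (j - mean_j) / np.sqrt(var_j)
    p = float(stats.norm.sf(z))
    return TrendTestResult(j, float(z), p, False, n, max_j)


def confusion_metrics(
    predicted: Sequence[bool],
    gold: Sequence[bool],
) -> tuple[float, float, ConfusionTable]:
    """Sensitivity and specificity of ``predicted`` against ``gold``.

    Returns NaN for a metric whose reference class is empty (undefined).
    """
    pred = np.asarray(predicted, dtype=bool)
    g = np.asarray(gold, dtype=bool)
    if pred.shape != g.shape:
        raise ValueError("classifications must cover the same children")
    table = ConfusionTable(
        tp=int((pred & g).sum()),
        fp=int((pred & ~g).sum()),
        tn=int((~pred & ~g).sum()),
        fn=int((~pred & g).sum()),
    )
    sens = table.tp / (table.tp + table.fn) if (table.tp + table.fn) else float("nan")
    spec = table.tn / (table.tn + table.fp) if (table.tn + table.fp) else float("nan")
    return sens, spec, table
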