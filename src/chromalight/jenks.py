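"""Exact Fisher-Jenks natural-breaks classification.

Finds the contiguous partition of sorted values into k classes minimizing the
total within-class sum of squared deviations about class means, by dynamic
programming over suffixes (exact, not the common heuristic refinements).
Breaks are reported as the upper value of each class except the last, so a
value v belongs to class j when break[j-2] < v <= break[j-1] (1-based j).

When several partitions tie on cost, the one whose first break is smallest is
chosen, recursively: the DP reconstruction walks left to right taking the
shortest optimal first class at each stage.
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegenerateClassesError, InvalidParameterError

__all__ = ["fisher_jenks_breaks", "jenks_partition", "partition_cost"]


def _interval_cost(prefix1: np.ndarray, prefix2: np.ndarray, i: int, j: np.ndarray):
    """SSD about the mean for x[i..j] inclusive, vectorized over j."""
    n = j - i + 1
    s1 = prefix1[j + 1] - prefix1[i]
    s2 = prefix2[j + 1] - prefix2[i]
    return s2 - s1 * s1 / n


def partition_cost(values: np.ndarray, boundaries: list[int]) -> float:
    """Total within-class SSD of sorted ``values`` split at the given
    boundaries (each boundary is the index of the last element of a class)."""
    x = np.sort(np.asarray(values, float))
    cost, start = 0.0, 0
    for b in list(boundaries) + [x.size - 1]:
        seg = x[start : b + 1]
        cost += float(np.sum((seg - seg.mean()) ** 2))
        start = b + 1
    return cost


def jenks_partition(values, k: int) -> tuple[list[int], float]:
    """Optimal class boundaries (last sorted index of classes 1..k-1) and cost."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    n = x.size
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if np.unique(x).size < k:
        raise DegenerateClassesError(
            f"only {np.unique(x).size} distinct values for k={k} classes"
        )
    prefix1 = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    idx = np.arange(n)

    # best[c][i]: minimal cost of splitting x[i:] into c classes
    best = np.empty((k + 1, n + 1))
    best[0, :] = np.inf
    best[0, n] = 0.0
    tail_n = n - idx
    tail_s1 = prefix1[n] - prefix1[idx]
    tail_s2 = prefix2[n] - prefix2[idx]
    best[1, :n] = tail_s2 - tail_s1 * tail_s1 / tail_n
    best[1, n] = np.inf
    for c in range(2, k + 1):
        best[c, n] = np.inf
        for i in range(n - 1, -1, -1):
            ends = idx[i : n - 1]  # last index of the first class
            if ends.size == 0:
                best[c, i] = np.inf
                continue
            costs = _interval_cost(prefix1, prefix2, i, ends) + best[c - 1, ends + 1]
            best[c, i] = np.min(costs)

    # left-to-right reconstruction; np.argmin takes the first optimum, i.e.
    # the shortest (smallest-break) first class at every stage
    boundaries: list[int] = []
    i = 0
    for c in range(k, 1, -1):
        ends = idx[i : n - 1]
        costs = _interval_cost(prefix1, prefix2, i, ends) + best[c - 1, ends + 1]
        j = int(ends[np.argmin(costs)])
        boundaries.append(j)
        i = j + 1
    return boundaries, float(best[k, 0])


def fisher_jenks_breaks(values, k: int) -> np.ndarray:
    """The k-1 ascending break values (upper bound of classes 1..k-1)."""
    x = np.sort(np.asarray(values, dtype=float).ravel())
    boundaries, _ = jenks_partition(x, k)
    return x[np.asarray(boundaries, dtype=int)]
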