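"""Sensitivity analysis of the optimal alignment: exact stability intervals.

Every monotone alignment path's cost is a linear function of the gap
penalty ρ (slope = number of gap columns, in the single-ρ regime) and of
any single similarity entry S_ij (slope 1 if the path pairs (i, j), else
0).  The maximal parameter interval over which a fixed optimal path stays
optimal is therefore obtained exactly by intersecting half-planes from
pairwise line comparisons against every competitor path — no numeric
bisection, no tolerance artifacts.  Competitors come from a complete
enumeration of monotone paths (their count is the Delannoy number D(m, n)),
which doubles as an independent brute-force oracle for the DP core.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf
from typing import Iterator

import numpy as np

from .align import AlignmentResult, GapModel

__all__ = [
    "StabilityInterval",
    "delannoy",
    "enumerate_alignments",
    "gap_stability_interval",
    "entry_stability_intervals",
]

_MAX_PATHS = 10**6


@dataclass(frozen=True)
class StabilityInterval:
    """Open interval (lower, upper) of one parameter preserving optimality.

    ``parameter`` identifies what varies: the string ``"rho"`` for the gap
    penalty, or an ``(i, j)`` tuple for a similarity entry.  A lower bound
    of 0.0 is open at 0 (the parameter itself is never negative); the upper
    bound may be ``inf``.
    """

    lower: float
    upper: float
    parameter: object = "rho"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"degenerate interval [{self.lower}, {self.upper}]")

    def __contains__(self, value: float) -> bool:
        return self.lower < value < self.upper


def delannoy(m: int, n: int) -> int:
    """Number of monotone lattice paths from (0,0) to (m,n) with unit
    right / down / diagonal steps — the number of global alignments."""
    D = np.zeros((m + 1, n + 1), dtype=object)
    D[0, :] = 1
    D[:, 0] = 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = D[i - 1, j] + D[i, j - 1] + D[i - 1, j - 1]
    return int(D[m, n])


def _path_cost(
    path: list[tuple[int | None, int | None]], S: np.ndarray, gaps: GapModel
) -> float:
    cost = 0.0
    prev_gap = None
    for (i, j) in path:
        if i is not None and j is not None:
            cost += S[i, j]
            prev_gap = None
        elif j is None:
            cost += gaps.rho_continue if prev_gap == "a" else gaps.rho_open
            prev_gap = "a"
        else:
            cost += gaps.rho_continue if prev_gap == "b" else gaps.rho_open
            prev_gap = "b"
    return cost


def _iter_paths(m: int, n: int) -> Iterator[list[tuple[int | None, int | None]]]:
    """Yield every monotone alignment path of an m×n instance."""
    stack: list[tuple[int, int, list]] = [(0, 0, [])]
    while stack:
        i, j, prefix = stack.pop()
        if i == m and j == n:
            yield prefix
            continue
        if i < m and j < n:
            stack.append((i + 1, j + 1, prefix + [(i, j)]))
        if i < m:
            stack.append((i + 1, j, prefix + [(i, None)]))
        if j < n:
            stack.append((i, j + 1, prefix + [(None, j)]))


def enumerate_alignments(
    S: np.ndarray, gaps: GapModel
) -> list[tuple[list[tuple[int | None, int | None]], float]]:
    """All monotone alignment paths of S with their affine-gap costs.

    Brute-force oracle for :func:`eigas.align.dp_align` and the substrate
    for the interval computations.  Refuses instances whose Delannoy path
    count exceeds 10⁶.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    count = delannoy(m, n)
    if count > _MAX_PATHS:
        raise ValueError(
            f"{m}x{n} instance has {count} alignment paths (> {_MAX_PATHS}); "
            "enumeration refused"
        )
    return [(path, _path_cost(path, S, gaps)) for path in _iter_paths(m, n)]


def _gap_columns(path) -> int:
    return sum(1 for (i, j) in path if i is None or j is None)


def _pair_set(path) -> frozenset:
    return frozenset((i, j) for (i, j) in path if i is not None and j is not None)


def _check_optimal(path, S, gaps, tol=1e-9) -> float:
    from .align import dp_align

    cost = _path_cost(path, np.asarray(S, float), gaps)
    best = dp_align(S, gaps).raw_value
    if cost > best + tol:
        raise ValueError(
            f"supplied path (cost {cost}) is not optimal (optimum {best})"
        )
    return cost


def gap_stability_interval(
    S: np.ndarray, rho: float, optimal_path
) -> StabilityInterval:
    """Maximal open interval of ρ over which ``optimal_path`` stays optimal.

    Single-penalty regime (ρ_o = ρ_c = ρ): each path's cost is a + g·ρ with
    g its gap-column count, so the interval endpoints are exact pairwise
    line intersections against every enumerated competitor.  Endpoints are
    excluded: a tie with a competitor marks the boundary.
    """
    S = np.asarray(S, dtype=float)
    gaps = GapModel.linear(rho)
    _check_optimal(optimal_path, S, gaps)
    a0 = _path_cost(optimal_path, S, GapModel.linear(0.0))
    g0 = _gap_columns(optimal_path)
    lower, upper = 0.0, inf
    pairs0 = _pair_set(optimal_path)
    for path in _iter_paths(*S.shape):
        if _pair_set(path) == pairs0 and _gap_columns(path) == g0:
            continue  # same cost line (or the path itself)
        a = _path_cost(path, S, GapModel.linear(0.0))
        g = _gap_columns(path)
        if g == g0:
            continue  # parallel lines; a0 <= a by optimality at rho
        crossing = (a - a0) / (g0 - g)
        if g < g0:
            upper = min(upper, crossing)
        else:
            lower = max(lower, crossing)
    lower = max(lower, 0.0)
    return StabilityInterval(lower=lower, upper=upper, parameter="rho")


def entry_stability_intervals(
    S: np.ndarray, gaps: GapModel, optimal_path
) -> list[list[StabilityInterval]]:
    """Stability interval of every similarity entry S_ij, all else fixed.

    Each path's cost is linear in the entry with slope 1 if the path pairs
    (i, j), slope 0 otherwise; the maximal interval for the reference path
    follows from exact pairwise comparisons.  Entries are clipped below at
    0 (dissimilarities are non-negative), matching the (0.0, ·) convention.
    """
    S = np.asarray(S, dtype=float)
    _check_optimal(optimal_path, S, gaps)
    m, n = S.shape
    cost0 = _path_cost(optimal_path, S, gaps)
    pairs0 = _pair_set(optimal_path)
    all_paths = [
        (p, _path_cost(p, S, gaps), _pair_set(p)) for p in _iter_paths(m, n)
    ]

    intervals: list[list[StabilityInterval]] = []
    for i in range(m):
        row: list[StabilityInterval] = []
        for j in range(n):
            v0 = S[i, j]
            on0 = (i, j) in pairs0
            a0 = cost0 - (v0 if on0 else 0.0)
            lower, upper = 0.0, inf
            for _, cost, pairs in all_paths:
                on = (i, j) in pairs
                if on == on0:
                    continue  # parallel in this entry
                a = cost - (v0 if on else 0.0)
                if on0:  # reference slope 1 vs competitor slope 0
                    upper = min(upper, a - a0)
                else:  # reference slope 0 vs competitor slope 1
                    lower = max(lower, a0 - a)
            row.append(
                StabilityInterval(lower=max(lower, 0.0), upper=upper, parameter=(i, j))
            )
        intervals.append(row)
    return intervals


def format_interval_matrix(intervals: list[list[StabilityInterval]]) -> str:
    """Render an entry-interval matrix as aligned plain text."""
    cells = [
        [
            "(%.4g, %s)" % (iv.lower, "inf" if iv.upper == inf else "%.4g" % iv.upper)
            for iv in row
        ]
        for row in intervals
    ]
    width = max(len(c) for row in cells for c in row)
    return "\n".join("  ".join(c.ljust(width) for c in row) for row in cells)


__all__.append("format_interval_matrix")
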