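"""Residue similarity and affine-gap global alignment by dynamic programming.

Two fingerprints are compared through the normalized eigenvalue
dissimilarity

    S_ij = |λ_i − λ_j| / |λ_i + λ_j|  ∈ [0, 1)  for positive eigenvalues,

and the optimal global (Needleman–Wunsch-style, terminal gaps penalized)
monotone alignment minimises the total cost under an affine gap model: a
gap run of length L costs ρ_o + (L−1)·ρ_c, where ρ_o opens and ρ_c
continues a gap.  Setting ρ_o = ρ_c = ρ recovers the classic single-penalty
recursion

    V_ij = min( V_{i−1,j} + ρ,  V_{i,j−1} + ρ,  V_{i−1,j−1} + S_ij ).

The whole-alignment comparison score is the raw optimal value divided by
the number of alignment columns; with S entries below one and penalties at
most one it lies in [0, 1], with 0 meaning identical fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

import numpy as np

from .spectral import SpectralFingerprint

__all__ = [
    "GapModel",
    "AlignmentResult",
    "similarity_matrix",
    "dp_align",
    "comparison_score",
    "write_alignment",
]

_INF = float("inf")


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalties: ``rho_open`` starts a gap run, ``rho_continue``
    extends it.  Equal penalties reduce to the single-ρ linear model."""

    rho_open: float
    rho_continue: float

    def __post_init__(self) -> None:
        for name in ("rho_open", "rho_continue"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")

    @classmethod
    def linear(cls, rho: float) -> "GapModel":
        return cls(rho, rho)

    @property
    def is_linear(self) -> bool:
        return self.rho_open == self.rho_continue


@dataclass
class AlignmentResult:
    """Optimal alignment path with its costs.

    ``path`` lists columns as ``(i, j)`` pairs with ``None`` marking a gap,
    indices 0-based; ``column_costs`` gives each column's contribution
    (similarity for a pair, ρ_o/ρ_c for gap columns); ``raw_value`` is their
    sum (the DP optimum); ``score`` is the length-normalized comparison
    value; ``value_matrix`` retains the (m+1)×(n+1) DP value table.
    """

    path: list[tuple[int | None, int | None]]
    column_costs: list[float]
    raw_value: float
    score: float
    value_matrix: np.ndarray = field(repr=False, default=None)
    gaps: GapModel | None = None


def similarity_matrix(
    fpA: SpectralFingerprint | np.ndarray, fpB: SpectralFingerprint | np.ndarray
) -> np.ndarray:
    """Pairwise normalized eigenvalue dissimilarities S_ij = |λi−λj|/|λi+λj|.

    Both inputs must carry strictly positive assigned eigenvalues (the
    denominator is then never zero and every entry lies in [0, 1)).
    Swapping the arguments transposes the matrix.
    """
    a = np.asarray(fpA.assigned if isinstance(fpA, SpectralFingerprint) else fpA, float)
    b = np.asarray(fpB.assigned if isinstance(fpB, SpectralFingerprint) else fpB, float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("similarity requires strictly positive eigenvalues")
    diff = np.abs(a[:, None] - b[None, :])
    summ = np.abs(a[:, None] + b[None, :])
    return diff / summ


def dp_align(S: np.ndarray, gaps: GapModel) -> AlignmentResult:
    """Globally optimal monotone alignment of an m×n cost matrix.

    Uses the three-state (match / gap-in-first / gap-in-second) affine
    recursion; terminal gaps are penalized through the boundary rows, whose
    values are cumulative gap-run costs ρ_o + (k−1)ρ_c.  Traceback is
    deterministic with tie preference diagonal > up > left.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.size == 0:
        raise ValueError("similarity matrix must be non-empty and 2-D")
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix must be finite")
    m, n = S.shape
    ro, rc = gaps.rho_open, gaps.rho_continue

    # state 0: last column pairs (i, j); state 1: last column (i, gap)
    # ("up"); state 2: last column (gap, j) ("left")
    M = np.full((m + 1, n + 1), _INF)
    Ga = np.full((m + 1, n + 1), _INF)  # gap in second sequence: consumes i
    Gb = np.full((m + 1, n + 1), _INF)  # gap in first sequence: consumes j
    M[0, 0] = 0.0
    # cumulative sums keep traceback equality tests exact in float arithmetic
    Ga[1, 0] = ro
    for i in range(2, m + 1):
        Ga[i, 0] = Ga[i - 1, 0] + rc
    Gb[0, 1] = ro
    for j in range(2, n + 1):
        Gb[0, j] = Gb[0, j - 1] + rc

    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best_prev = min(M[i - 1, j - 1], Ga[i - 1, j - 1], Gb[i - 1, j - 1])
            M[i, j] = S[i - 1, j - 1] + best_prev
            Ga[i, j] = min(M[i - 1, j] + ro, Ga[i - 1, j] + rc, Gb[i - 1, j] + ro)
            Gb[i, j] = min(M[i, j - 1] + ro, Gb[i, j - 1] + rc, Ga[i, j - 1] + ro)

    V = np.minimum(np.minimum(M, Ga), Gb)
    V[0, 0] = 0.0

    # deterministic traceback: at every decision, prefer diagonal (pair),
    # then up (i, gap), then left (gap, j)
    def pick_state(i: int, j: int) -> int:
        vals = (M[i, j], Ga[i, j], Gb[i, j])
        best = min(vals)
        for s in (0, 1, 2):
            if vals[s] == best:
                return s
        raise AssertionError

    path: list[tuple[int | None, int | None]] = []
    i, j = m, n
    state = pick_state(i, j)
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = pick_state(i, j)
        elif state == 1:
            path.append((i - 1, None))
            target = Ga[i, j]
            if M[i - 1, j] + ro == target:
                state = 0
            elif Ga[i - 1, j] + rc == target:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            path.append((None, j - 1))
            target = Gb[i, j]
            if M[i, j - 1] + ro == target:
                state = 0
            elif Gb[i, j - 1] + rc == target:
                state = 2
            else:
                state = 1
            j -= 1
    path.reverse()

    costs: list[float] = []
    prev_gap: str | None = None
    for (pi, pj) in path:
        if pi is not None and pj is not None:
            costs.append(float(S[pi, pj]))
            prev_gap = None
        elif pj is None:
            costs.append(rc if prev_gap == "a" else ro)
            prev_gap = "a"
        else:
            costs.append(rc if prev_gap == "b" else ro)
            prev_gap = "b"

    raw = float(sum(costs))
    result = AlignmentResult(
        path=path,
        column_costs=costs,
        raw_value=raw,
        score=raw / len(path),
        value_matrix=V,
        gaps=gaps,
    )
    if abs(raw - V[m, n]) > 1e-9 * max(1.0, abs(raw)):
        raise AssertionError(
            f"traceback cost {raw} disagrees with DP optimum {V[m, n]}"
        )
    return result


def comparison_score(result: AlignmentResult) -> float:
    """Length-normalized alignment score: raw optimal value over the number
    of alignment columns.  Zero for a self-alignment; at most one when all
    similarities and penalties are ≤ 1."""
    return result.raw_value / len(result.path)


def write_alignment(
    result: AlignmentResult,
    destination: str | IO[str],
    chain_a: str = "A",
    chain_b: str = "B",
    cutoff: float | None = None,
) -> None:
    """Write an alignment as a plain-text table, one path column per line."""
    g = result.gaps
    header = [
        f"# chains\t{chain_a}\t{chain_b}",
        f"# kappa\t{cutoff if cutoff is not None else 'NA'}",
        f"# rho_open\t{g.rho_open if g else 'NA'}",
        f"# rho_continue\t{g.rho_continue if g else 'NA'}",
        f"# raw_value\t{result.raw_value:.12g}",
        f"# score\t{result.score:.12g}",
    ]
    rows = [
        "{}\t{}\t{:.12g}".format(
            "-" if i is None else i, "-" if j is None else j, c
        )
        for (i, j), c in zip(result.path, result.column_costs)
    ]
    text = "\n".join(header + rows) + "\n"
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)
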