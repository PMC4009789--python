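"""ROC analysis of all-against-all comparison scores.

Pairwise alignment scores (lower = more structurally similar) are turned
into a binary classifier by thresholding: a pair is predicted to share a
family when its score is at most τ.  Sweeping τ traces a ROC curve — the
true positive rate among same-family pairs against the false positive rate
among different-family pairs — whose area (AUROC) summarises family
recognition (1 is perfect, 0.5 is random).  The best operating point is
the curve point closest to perfect classification (FPR 0, TPR 1).

A deliberately idiosyncratic trimmed bootstrap interval is also provided:
from a set of sampled AUROCs, drop exactly the single highest and lowest
value and report the range of the remainder (with 40 samples this is a 95%
interval).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "RocCurve",
    "roc_points",
    "auroc",
    "best_operating_point",
    "trimmed_ci",
    "read_score_table",
    "write_score_table",
    "write_roc",
]


@dataclass
class ScoreTable:
    """Symmetric table of pairwise comparison scores with family labels.

    ``scores`` is a square DataFrame indexed by chain id on both axes with
    a zero diagonal; ``families`` maps every chain id to its family label.
    """

    scores: pd.DataFrame
    families: Mapping[str, str]

    def __post_init__(self) -> None:
        df = self.scores
        if not df.index.equals(df.columns):
            raise ValueError("score table must have matching row/column ids")
        vals = df.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("score table must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValueError("self-comparison scores must be 0")
        missing = [c for c in df.index if c not in self.families]
        if missing:
            raise ValueError(f"missing family labels for {missing}")

    def pairs(self) -> Iterator[tuple[str, str, float, bool]]:
        """Yield (id_a, id_b, score, same_family) for each unordered pair."""
        ids = list(self.scores.index)
        for a_idx in range(len(ids)):
            for b_idx in range(a_idx + 1, len(ids)):
                a, b = ids[a_idx], ids[b_idx]
                yield a, b, float(self.scores.iat[a_idx, b_idx]), (
                    self.families[a] == self.families[b]
                )

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Condensed (scores, same_family) arrays over unordered pairs."""
        rows = list(self.pairs())
        scores = np.array([r[2] for r in rows])
        same = np.array([r[3] for r in rows], dtype=bool)
        return scores, same


@dataclass
class RocCurve:
    """Parametric ROC curve over the decision threshold τ.

    ``tau``, ``fpr`` and ``tpr`` are parallel arrays sorted by τ; ``auroc``
    is the trapezoidal area under the (FPR, TPR) curve; ``best`` is the
    operating point (τ*, FPR*, TPR*) nearest to (0, 1) and
    ``best_distance`` its Euclidean distance to perfect classification.
    """

    tau: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    best: tuple[float, float, float]
    best_distance: float


def _rates(scores: np.ndarray, same: np.ndarray, tau: float) -> tuple[float, float]:
    predicted = scores <= tau
    tpr = np.sum(predicted & same) / np.sum(same)
    fpr = np.sum(predicted & ~same) / np.sum(~same)
    return float(fpr), float(tpr)


def roc_points(table: ScoreTable) -> RocCurve:
    """ROC curve of a score table under the rule "same family iff score ≤ τ".

    Candidate thresholds are the distinct scores, the midpoints between
    consecutive distinct scores, and sentinels below the minimum and above
    the maximum, so the curve attains (0, 0) below every score and (1, 1)
    at and beyond the largest.
    """
    scores, same = table.pair_arrays()
    if len(scores) < 1 or same.all() or (~same).all():
        raise ValueError(
            "ROC needs at least one same-family and one different-family pair"
        )
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    span = max(distinct[-1] - distinct[0], 1.0)
    taus = np.unique(
        np.concatenate(
            [distinct, mids, [distinct[0] - 0.05 * span, distinct[-1] + 0.05 * span]]
        )
    )
    fpr = np.empty_like(taus)
    tpr = np.empty_like(taus)
    for k, t in enumerate(taus):
        fpr[k], tpr[k] = _rates(scores, same, t)

    order = np.argsort(fpr, kind="stable")
    area = float(np.trapezoid(tpr[order], fpr[order]))

    dist = np.hypot(fpr, 1.0 - tpr)
    k_best = int(np.argmin(dist))  # first minimum = smallest tau (taus sorted)
    best = (float(taus[k_best]), float(fpr[k_best]), float(tpr[k_best]))
    return RocCurve(
        tau=taus, fpr=fpr, tpr=tpr, auroc=area, best=best, best_distance=float(dist[k_best])
    )


def auroc(curve: RocCurve) -> float:
    """Area under the ROC curve (trapezoidal rule over FPR-sorted points).

    Equal to the probability that a random same-family pair scores below a
    random different-family pair, with ties counted half.
    """
    return curve.auroc


def best_operating_point(curve: RocCurve) -> tuple[float, float, float]:
    """The (τ*, FPR*, TPR*) minimizing distance to perfect classification
    (0, 1); ties broken toward the smaller τ."""
    return curve.best


def trimmed_ci(aurocs: Sequence[float]) -> tuple[float, float]:
    """Trimmed bootstrap interval: drop exactly one highest and one lowest
    value, return (min, max) of the remainder.

    With 40 samples this yields a 95% interval; other sample counts are
    accepted (logged) but shift the nominal coverage.
    """
    vals = sorted(float(v) for v in aurocs)
    if len(vals) < 3:
        raise ValueError("trimmed interval needs at least 3 values")
    if len(vals) != 40:
        logger.info(
            "trimmed interval over %d values (40 gives nominal 95%% coverage)",
            len(vals),
        )
    rest = vals[1:-1]
    return rest[0], rest[-1]


def write_score_table(table: ScoreTable, destination: str | IO[str]) -> None:
    """Write scores as a labelled TSV matrix followed by a family map."""

    def _write(fh: IO[str]) -> None:
        table.scores.to_csv(fh, sep="\t")
        fh.write("#FAMILIES\n")
        for cid in table.scores.index:
            fh.write(f"{cid}\t{table.families[cid]}\n")

    if isinstance(destination, str):
        with open(destination, "w") as fh:
            _write(fh)
    else:
        _write(destination)


def read_score_table(source: str | IO[str]) -> ScoreTable:
    """Read a score table written by :func:`write_score_table`."""
    if isinstance(source, str):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()
    matrix_part, _, family_part = text.partition("#FAMILIES\n")
    from io import StringIO

    df = pd.read_csv(StringIO(matrix_part), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    families = {}
    for line in family_part.splitlines():
        if line.strip():
            cid, fam = line.split("\t")
            families[cid] = fam
    return ScoreTable(scores=df, families=families)


def write_roc(curve: RocCurve, destination: str | IO[str]) -> None:
    """Write a ROC curve as three-column text (tau, FPR, TPR)."""
    lines = ["tau\tfpr\ttpr"] + [
        f"{t:.12g}\t{f:.12g}\t{p:.12g}"
        for t, f, p in zip(curve.tau, curve.fpr, curve.tpr)
    ]
    text = "\n".join(lines) + "\n"
    if isinstance(destination, str):
        with open(destination, "w") as fh:
            fh.write(text)
    else:
        destination.write(text)
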