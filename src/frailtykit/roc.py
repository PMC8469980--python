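"""ROC cut-point analysis for integer-valued screening scores.

Builds the operating-characteristics table over every integer threshold
("test positive iff score >= c"), computes the area under the empirical ROC
curve, selects the Youden-optimal threshold, and reconstructs a per-score
distribution from a published table of cumulative sensitivities and
false-positive fractions.

The AUC is computed two ways — the tie-corrected rank statistic
P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg), and the trapezoidal
area under the empirical ROC polygon — and the two are asserted to agree to
1e-12 on every call.  They are mathematically identical on empirical data;
computing both guards against off-by-one threshold bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .diagnostics import ContingencyTable2x2, diag_metrics

__all__ = [
    "ScoreDistribution",
    "CutpointRow",
    "RocCurve",
    "cutpoint_table",
    "auc",
    "optimal_cutpoint",
    "reconstruct_distribution",
]


@dataclass(frozen=True)
class ScoreDistribution:
    """Per-integer-score patient counts, split by condition status.

    ``pos_counts[s]`` / ``neg_counts[s]`` are the numbers of condition-positive
    and condition-negative patients with score exactly ``s``, for
    ``s = 0 .. max_score``.
    """

    pos_counts: tuple[int, ...]
    neg_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.pos_counts) != len(self.neg_counts):
            raise ValueError("pos_counts and neg_counts must cover the same score range")
        if len(self.pos_counts) == 0:
            raise ValueError("score range must be nonempty")
        if any(c < 0 for c in self.pos_counts + self.neg_counts):
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_mappings(
        cls,
        pos: Mapping[int, int],
        neg: Mapping[int, int],
        max_score: Optional[int] = None,
    ) -> "ScoreDistribution":
        top = max(list(pos) + list(neg) + [max_score or 0])
        return cls(
            pos_counts=tuple(int(pos.get(s, 0)) for s in range(top + 1)),
            neg_counts=tuple(int(neg.get(s, 0)) for s in range(top + 1)),
        )

    @classmethod
    def from_scores(cls, scores: Sequence[int], condition: Sequence[bool]) -> "ScoreDistribution":
        scores = np.asarray(scores, dtype=int)
        condition = np.asarray(condition, dtype=bool)
        if scores.shape != condition.shape:
            raise ValueError("scores and condition must have equal length")
        if scores.min(initial=0) < 0:
            raise ValueError("scores must be nonnegative integers")
        top = int(scores.max(initial=0))
        pos = np.bincount(scores[condition], minlength=top + 1)
        neg = np.bincount(scores[~condition], minlength=top + 1)
        return cls(pos_counts=tuple(int(c) for c in pos), neg_counts=tuple(int(c) for c in neg))

    @property
    def max_score(self) -> int:
        return len(self.pos_counts) - 1

    @property
    def n_pos(self) -> int:
        return sum(self.pos_counts)

    @property
    def n_neg(self) -> int:
        return sum(self.neg_counts)

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    def pooled_scores(self) -> np.ndarray:
        """All patient scores (both groups) as a flat vector."""
        reps = [p + q for p, q in zip(self.pos_counts, self.neg_counts)]
        return np.repeat(np.arange(self.max_score + 1), reps)

    def table_at(self, cutpoint: int) -> ContingencyTable2x2:
        """2x2 table induced by declaring patients test-positive iff score >= cutpoint."""
        tp = sum(self.pos_counts[cutpoint:])
        fp = sum(self.neg_counts[cutpoint:])
        return ContingencyTable2x2(tp=tp, fp=fp, fn=self.n_pos - tp, tn=self.n_neg - fp)


@dataclass(frozen=True)
class CutpointRow:
    """Operating characteristics of the rule 'positive iff score >= cutpoint'."""

    cutpoint: int
    se: float
    sp: float
    ppv: Optional[float]
    npv: Optional[float]

    @property
    def one_minus_sp(self) -> float:
        return 1.0 - self.sp

    @property
    def youden(self) -> float:
        return self.se + self.sp - 1.0


@dataclass(frozen=True)
class RocCurve:
    """Ordered cut-point rows for c = 1 .. max_score (monotone by construction)."""

    rows: tuple[CutpointRow, ...]
    n_pos: int
    n_neg: int

    def points(self) -> np.ndarray:
        """ROC polygon vertices (1-sp, se), including the trivial (0,0) and (1,1)."""
        pts = [(1.0, 1.0)] + [(r.one_minus_sp, r.se) for r in self.rows] + [(0.0, 0.0)]
        return np.array(sorted(pts))


def _check_groups(dist: ScoreDistribution) -> None:
    if dist.n_pos < 1 or dist.n_neg < 1:
        raise ValueError(
            f"both groups must be nonempty (n_pos={dist.n_pos}, n_neg={dist.n_neg})"
        )


def cutpoint_table(distribution: ScoreDistribution) -> RocCurve:
    """Operating characteristics at every integer cutpoint c = 1 .. max_score."""
    _check_groups(distribution)
    rows = []
    for c in range(1, distribution.max_score + 1):
        m = diag_metrics(distribution.table_at(c))
        assert m.sensitivity is not None and m.specificity is not None
        rows.append(CutpointRow(cutpoint=c, se=m.sensitivity, sp=m.specificity,
                                ppv=m.ppv, npv=m.npv))
    return RocCurve(rows=tuple(rows), n_pos=distribution.n_pos, n_neg=distribution.n_neg)


def _auc_rank(dist: ScoreDistribution) -> float:
    pos = np.asarray(dist.pos_counts, dtype=float)
    neg = np.asarray(dist.neg_counts, dtype=float)
    neg_below = np.concatenate([[0.0], np.cumsum(neg)[:-1]])  # negatives scoring < s
    wins = float(np.sum(pos * neg_below))
    ties = float(np.sum(pos * neg))
    return (wins + 0.5 * ties) / (dist.n_pos * dist.n_neg)


def _auc_trapezoid(dist: ScoreDistribution) -> float:
    pts = cutpoint_table(dist).points()
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auc(distribution: ScoreDistribution) -> float:
    """Area under the empirical ROC curve.

    Tie-corrected rank form, cross-checked against the trapezoidal area under
    the ROC polygon (agreement to 1e-12 is asserted).
    """
    _check_groups(distribution)
    a_rank = _auc_rank(distribution)
    a_trap = _auc_trapezoid(distribution)
    if abs(a_rank - a_trap) > 1e-12:
        raise AssertionError(
            f"rank AUC {a_rank!r} and trapezoid AUC {a_trap!r} disagree beyond 1e-12"
        )
    return a_rank


def optimal_cutpoint(curve: RocCurve) -> int:
    """The cutpoint maximizing the Youden index (se + sp - 1).

    Ties are broken toward the lowest cutpoint, favouring sensitivity — the
    natural choice for a screening instrument.
    """
    if not curve.rows:
        raise ValueError("curve has no cutpoint rows")
    best = max(curve.rows, key=lambda r: (r.youden, -r.cutpoint))
    return best.cutpoint


def reconstruct_distribution(
    cumulative_rows: Sequence[tuple[int, float, float]],
    n_pos: int,
    n_neg: int,
    tol: float = 0.02,
) -> ScoreDistribution:
    """Recover per-score counts from cumulative (cutpoint, se, 1-sp) rows.

    Each row gives, at integer cutpoint ``c``, the fraction of
    condition-positives (``se``) and condition-negatives (``one_minus_sp``)
    with score >= c.  Scaling those fractions by the group sizes must land
    within ``tol`` patients of an integer (the published fractions are exact
    counts over the group size, rounded for display); adjacent cumulative
    counts are then differenced to yield per-score counts.  Scores at or above
    the last tabulated cutpoint are collapsed onto that cutpoint's value.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("group sizes must be positive")
    rows = sorted(cumulative_rows)
    cutpoints = [c for c, _, _ in rows]
    if cutpoints != list(range(cutpoints[0], cutpoints[0] + len(rows))):
        raise ValueError(f"cutpoints must be consecutive integers, got {cutpoints}")

    def cum_counts(fractions: Sequence[float], size: int, label: str) -> list[int]:
        counts = []
        for (c, _, _), frac in zip(rows, fractions):
            scaled = frac * size
            nearest = round(scaled)
            if abs(scaled - nearest) >= tol:
                raise ValueError(
                    f"cutpoint {c}: {label} fraction {frac} scales to {scaled:.4f}, "
                    f"not within {tol} of an integer"
                )
            counts.append(int(nearest))
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"{label} cumulative counts must be non-increasing: {counts}")
        if counts[0] > size:
            raise ValueError(f"{label} cumulative count {counts[0]} exceeds group size {size}")
        return counts

    cum_pos = cum_counts([se for _, se, _ in rows], n_pos, "sensitivity")
    cum_neg = cum_counts([fpr for _, _, fpr in rows], n_neg, "1-specificity")

    first, last = cutpoints[0], cutpoints[-1]
    pos: dict[int, int] = {}
    neg: dict[int, int] = {}
    if first > 0:
        pos[first - 1] = n_pos - cum_pos[0]
        neg[first - 1] = n_neg - cum_neg[0]
    for i, c in enumerate(cutpoints[:-1]):
        pos[c] = cum_pos[i] - cum_pos[i + 1]
        neg[c] = cum_neg[i] - cum_neg[i + 1]
    pos[last] = cum_pos[-1]  # scores >= last cutpoint collapse here
    neg[last] = cum_neg[-1]
    return ScoreDistribution.from_mappings(pos, neg, max_score=last)
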