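"""2x2 diagnostic-accuracy metrics, risk ratios, association tests, CIs.

Everything here operates on a :class:`ContingencyTable2x2` crossing a binary
screening item (test) against a binary frailty criterion (condition):

======================  =================  =================
                        condition +        condition -
test +                  tp                 fp
test -                  fn                 tn
======================  =================  =================

Metrics are stored as proportions in [0, 1]; rendering as percentages happens
only at the report layer.  A metric whose denominator is zero is returned as
``None`` (explicitly undefined) rather than silently coerced to 0, so batch
reports over many items never abort or fabricate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "DiagnosticSummary",
    "AssociationResult",
    "crosstab",
    "diag_metrics",
    "risk_ratio",
    "association_p",
    "wilson_ci",
    "rr_ci",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts crossing a binary test against a binary condition."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """2x2 array with test status on rows, condition status on columns."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])

    def swapped_test(self) -> "ContingencyTable2x2":
        """The table with test-positive and test-negative rows exchanged."""
        return ContingencyTable2x2(self.fn, self.tn, self.tp, self.fp)


@dataclass(frozen=True)
class DiagnosticSummary:
    """Operating characteristics of a binary test; ``None`` marks an undefined metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    youden: Optional[float]
    risk_ratio: Optional[float]  # may be math.inf (flagged-infinite)
    p_value: float
    p_method: str
    ci: dict[str, Optional[tuple[float, float]]]
    undefined: tuple[str, ...]


@dataclass(frozen=True)
class AssociationResult:
    """Two-sided association p-value and the test that produced it."""

    p_value: float
    method: str  # "fisher_exact" | "chi2_yates" | "degenerate"
    degenerate: bool = False


def crosstab(test_positive: Sequence, condition_positive: Sequence) -> ContingencyTable2x2:
    """Cross-tabulate paired boolean vectors into a 2x2 table."""
    t = np.asarray(test_positive)
    c = np.asarray(condition_positive)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {t.shape} and {c.shape}")
    if t.size == 0:
        raise ValueError("vectors must be nonempty")
    for name, v in (("test", t), ("condition", c)):
        if v.dtype == object and any(x is None for x in v):
            raise ValueError(f"{name} vector contains missing entries")
        if np.issubdtype(v.dtype, np.floating) and np.isnan(v).any():
            raise ValueError(f"{name} vector contains missing entries")
    t = t.astype(bool)
    c = c.astype(bool)
    return ContingencyTable2x2(
        tp=int(np.sum(t & c)),
        fp=int(np.sum(t & ~c)),
        fn=int(np.sum(~t & c)),
        tn=int(np.sum(~t & ~c)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def diag_metrics(table: ContingencyTable2x2, ci_level: float = 0.95) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV, NPV, Youden index, RR and p-value for a 2x2 table.

    Wilson score intervals accompany each proportion and a Katz log interval
    the risk ratio; intervals for undefined metrics are ``None``.
    """
    se = _ratio(table.tp, table.tp + table.fn)
    sp = _ratio(table.tn, table.tn + table.fp)
    ppv = _ratio(table.tp, table.tp + table.fp)
    npv = _ratio(table.tn, table.tn + table.fn)
    youden = se + sp - 1 if se is not None and sp is not None else None
    rr = risk_ratio(table)
    assoc = association_p(table)

    ci: dict[str, Optional[tuple[float, float]]] = {}
    for name, (k, m) in {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }.items():
        ci[name] = wilson_ci(k, m, ci_level) if m > 0 else None
    try:
        ci["risk_ratio"] = rr_ci(table, ci_level)
    except ValueError:
        ci["risk_ratio"] = None

    metrics = {"sensitivity": se, "specificity": sp, "ppv": ppv, "npv": npv,
               "youden": youden, "risk_ratio": rr}
    undefined = tuple(name for name, value in metrics.items() if value is None)
    return DiagnosticSummary(
        sensitivity=se, specificity=sp, ppv=ppv, npv=npv, youden=youden,
        risk_ratio=rr, p_value=assoc.p_value, p_method=assoc.method,
        ci=ci, undefined=undefined,
    )


def risk_ratio(table: ContingencyTable2x2) -> Optional[float]:
    """Risk of the condition among test-positives over risk among test-negatives.

    RR = (tp / (tp + fp)) / (fn / (fn + tn)).  Returns ``math.inf`` when the
    test-negative risk is zero but the test-positive risk is not, and ``None``
    (undefined) when either group is empty or both risks are zero.
    """
    if table.tp + table.fp == 0 or table.fn + table.tn == 0:
        return None
    risk_pos = table.tp / (table.tp + table.fp)
    risk_neg = table.fn / (table.fn + table.tn)
    if risk_neg == 0:
        return math.inf if risk_pos > 0 else None
    return risk_pos / risk_neg


def expected_counts(table: ContingencyTable2x2) -> np.ndarray:
    """Expected cell counts under independence of test and condition."""
    a = table.as_array()
    return np.outer(a.sum(axis=1), a.sum(axis=0)) / table.n


def association_p(table: ContingencyTable2x2) -> AssociationResult:
    """Two-sided test of association between test and condition.

    Fisher's exact test (point-probability rule) when any expected count is
    below 5, otherwise the chi-square test with Yates continuity correction —
    the standard small-count decision rule.  Degenerate margins (an empty row
    or column) carry no information and return p = 1 with a flag.
    """
    a = table.as_array()
    if (a.sum(axis=0) == 0).any() or (a.sum(axis=1) == 0).any():
        return AssociationResult(p_value=1.0, method="degenerate", degenerate=True)
    if (expected_counts(table) < 5).any():
        p = stats.fisher_exact(a, alternative="two-sided").pvalue
        return AssociationResult(p_value=float(p), method="fisher_exact")
    p = stats.chi2_contingency(a, correction=True)[1]
    return AssociationResult(p_value=float(p), method="chi2_yates")


def wilson_ci(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not 0 <= successes <= trials or trials < 1:
        raise ValueError(f"need 0 <= successes <= trials >= 1, got {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2)
    phat = successes / trials
    denom = 1 + z**2 / trials
    centre = (phat + z**2 / (2 * trials)) / denom
    half = z * math.sqrt(phat * (1 - phat) / trials + z**2 / (4 * trials**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def rr_ci(table: ContingencyTable2x2, level: float = 0.95) -> tuple[float, float]:
    """Katz log-method confidence interval for the risk ratio.

    Requires all four cells positive; no continuity adjustment is applied for
    zero cells (the interval is reported as undefined instead).
    """
    if min(table.tp, table.fp, table.fn, table.tn) == 0:
        raise ValueError("Katz interval undefined with a zero cell")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    rr = risk_ratio(table)
    assert rr is not None and math.isfinite(rr)
    z = stats.norm.ppf(0.5 + level / 2)
    se_log = math.sqrt(
        1 / table.tp - 1 / (table.tp + table.fp) + 1 / table.fn - 1 / (table.fn + table.tn)
    )
    return (rr * math.exp(-z * se_log), rr * math.exp(z * se_log))
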