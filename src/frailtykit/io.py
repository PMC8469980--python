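"""Cohort file I/O and the full scale-validation report.

Cohort files are comma-separated UTF-8 text with a header row and one row per
patient: a unique ``patient_id``, six ``zfs_*`` binary columns, thirteen
``msega_*`` ordinal columns, and optional demographics.  Binary answers are
serialized as 0/1; the reader also accepts yes/no (and oui/non)
case-insensitively and normalises.  Decimal separators are always dots.

``validation_report`` assembles the complete diagnostic validation of the ZFS
against the mSEGA frailty criterion on a cohort: per-item 2x2 accuracy with
risk ratios and association tests (against both frailty definitions), the
integer cut-point table with AUC and the Youden-optimal threshold, the
cross-scale correlation with its Fisher-z interval, and cohort descriptives.
Every rendered number is backed by the same machine-readable value exposed by
``ValidationReport.to_dict`` — there is one source of truth per figure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .association import pearson_ci, pearson_r
from .diagnostics import DiagnosticSummary, crosstab, diag_metrics
from .roc import RocCurve, ScoreDistribution, auc, cutpoint_table, optimal_cutpoint
from .scales import (
    MSEGA_ITEMS,
    ZFS_ITEMS,
    InvalidResponseError,
    cohort_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["read_cohort", "write_cohort", "validation_report", "ValidationReport",
           "EXIT_OK", "EXIT_USAGE", "EXIT_VALIDATION", "EXIT_DEGENERATE"]

# Exit-status contract for the CLI and for report consumers.
EXIT_OK = 0
EXIT_USAGE = 1
EXIT_VALIDATION = 2
EXIT_DEGENERATE = 3

ZFS_COLUMNS = tuple(f"zfs_{name}" for name in ZFS_ITEMS)
MSEGA_COLUMNS = tuple(f"msega_{name}" for name in MSEGA_ITEMS)
DEMOGRAPHIC_COLUMNS = ("age", "sex", "weight_kg", "height_cm", "n_medications",
                       "charlson", "adl", "iadl")
CANONICAL_COLUMNS = ("patient_id",) + ZFS_COLUMNS + MSEGA_COLUMNS + DEMOGRAPHIC_COLUMNS

_YES = {"1", "yes", "y", "oui", "true"}
_NO = {"0", "no", "n", "non", "false"}


def _normalise_binary_cell(value: object, row: object, column: str, strict: bool) -> object:
    if pd.isna(value):
        return np.nan
    if isinstance(value, (int, float, np.integer, np.floating, np.bool_)):
        iv = int(value)
        if iv == value and iv in (0, 1):
            return iv
        raise InvalidResponseError(
            f"row {row!r}, column {column!r}: value {value!r} is not a yes/no answer"
        )
    token = str(value).strip().lower()
    if token in _YES:
        return 1
    if token in _NO:
        return 0
    raise InvalidResponseError(
        f"row {row!r}, column {column!r}: value {value!r} is not a yes/no answer"
    )


def read_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort table.

    In strict mode any incomplete or out-of-alphabet scale cell is an error
    naming the row and column; otherwise rows with incomplete scale data are
    dropped, with their identifiers logged and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    if "patient_id" not in df.columns:
        raise InvalidResponseError(f"{path}: missing required column 'patient_id'")
    missing = [c for c in ZFS_COLUMNS + MSEGA_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidResponseError(f"{path}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    if unknown:
        raise InvalidResponseError(f"{path}: unknown columns {unknown}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise InvalidResponseError(f"{path}: duplicate patient_ids {dupes}")
    if len(df) == 0:
        raise InvalidResponseError(f"{path}: cohort contains no rows")

    bad_rows: set[int] = set()
    for col in ZFS_COLUMNS:
        for i, value in df[col].items():
            try:
                df.at[i, col] = _normalise_binary_cell(value, df.at[i, "patient_id"], col, strict)
            except InvalidResponseError:
                if strict:
                    raise
                bad_rows.add(i)
    for col in MSEGA_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        out = ~numeric.isin([0, 1, 2])
        bad_present = out & df[col].notna()
        if bad_present.any():
            i = int(bad_present.idxmax())
            if strict:
                raise InvalidResponseError(
                    f"row {df.at[i, 'patient_id']!r}, column {col!r}: "
                    f"value {df.at[i, col]!r} not in {{0, 1, 2}}"
                )
            bad_rows.update(df.index[bad_present])
        df[col] = numeric

    scale_cols = list(ZFS_COLUMNS + MSEGA_COLUMNS)
    incomplete = df[scale_cols].isna().any(axis=1)
    if incomplete.any():
        if strict:
            i = int(incomplete.idxmax())
            col = df.loc[i, scale_cols].isna().idxmax()
            raise InvalidResponseError(
                f"row {df.at[i, 'patient_id']!r}: missing value in column {col!r}"
            )
        bad_rows.update(df.index[incomplete])
    if bad_rows:
        dropped = df.loc[sorted(bad_rows), "patient_id"].tolist()
        logger.warning("dropping %d incomplete rows: %s", len(dropped), dropped)
        df = df.drop(index=sorted(bad_rows)).reset_index(drop=True)
        if len(df) == 0:
            raise InvalidResponseError(f"{path}: no complete rows remain")
    df[scale_cols] = df[scale_cols].astype(int)
    return df


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    """Write a cohort in canonical column order (UTF-8, dot decimals, newline-terminated)."""
    df = cohort.copy()
    ordered = [c for c in CANONICAL_COLUMNS if c in df.columns]
    extras = [c for c in df.columns if c not in ordered]
    if extras:
        raise InvalidResponseError(f"unknown columns {extras}")
    for col in DEMOGRAPHIC_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df = df[[c for c in CANONICAL_COLUMNS]]
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


@dataclass(frozen=True)
class ValidationReport:
    """Machine-readable validation of the ZFS against the mSEGA criterion."""

    n: int
    zfs_threshold: int
    msega_cutoff: int
    item_vs_sega: dict[str, DiagnosticSummary]
    item_vs_zfs: dict[str, DiagnosticSummary]
    curve: Optional[RocCurve]
    auc: Optional[float]
    optimal_cutpoint: Optional[int]
    totals_r: Optional[float]
    totals_ci: Optional[tuple[float, float]]
    descriptives: dict[str, object]
    degenerate: bool
    degenerate_sections: tuple[str, ...]
    metadata: dict[str, object] = field(default_factory=dict)

    @property
    def exit_status(self) -> int:
        return EXIT_DEGENERATE if self.degenerate else EXIT_OK

    def to_dict(self) -> dict:
        def summary_dict(s: DiagnosticSummary) -> dict:
            return {
                "sensitivity": s.sensitivity,
                "specificity": s.specificity,
                "ppv": s.ppv,
                "npv": s.npv,
                "youden": s.youden,
                "risk_ratio": None if s.risk_ratio is None
                else ("inf" if math.isinf(s.risk_ratio) else s.risk_ratio),
                "p_value": s.p_value,
                "p_method": s.p_method,
                "ci": {k: list(v) if v else None for k, v in s.ci.items()},
                "undefined": list(s.undefined),
            }

        return {
            "n": self.n,
            "zfs_threshold": self.zfs_threshold,
            "msega_cutoff": self.msega_cutoff,
            "item_vs_sega": {k: summary_dict(v) for k, v in self.item_vs_sega.items()},
            "item_vs_zfs": {k: summary_dict(v) for k, v in self.item_vs_zfs.items()},
            "cutpoints": None if self.curve is None else [
                {"cutpoint": r.cutpoint, "se": r.se, "sp": r.sp,
                 "one_minus_sp": r.one_minus_sp, "youden": r.youden,
                 "ppv": r.ppv, "npv": r.npv}
                for r in self.curve.rows
            ],
            "auc": self.auc,
            "optimal_cutpoint": self.optimal_cutpoint,
            "totals_r": self.totals_r,
            "totals_ci": list(self.totals_ci) if self.totals_ci else None,
            "descriptives": self.descriptives,
            "degenerate": self.degenerate,
            "degenerate_sections": list(self.degenerate_sections),
            "metadata": self.metadata,
        }

    def render(self) -> str:
        """Plain-text report; every figure mirrors ``to_dict`` exactly."""
        def pct(x: Optional[float]) -> str:
            return "undefined" if x is None else f"{100 * x:.0f}%"

        lines = [
            f"ZFS validation report (frailtykit {self.metadata.get('version', _version)})",
            f"cohort n = {self.n}; ZFS frail iff score >= {self.zfs_threshold}; "
            f"mSEGA frail iff total > {self.msega_cutoff}",
            "",
        ]
        d = self.descriptives
        lines.append(
            f"ZFS total: mean {d['zfs_mean']:.2f} (sd {d['zfs_sd']:.2f}); "
            f"classes robust/pre-frail/frail = {d['zfs_classes']['robust']}"
            f"/{d['zfs_classes']['pre_frail']}/{d['zfs_classes']['frail']}"
        )
        lines.append(
            f"mSEGA total: mean {d['msega_mean']:.2f} (sd {d['msega_sd']:.2f}); "
            f"frail {d['msega_frail_n']} ({pct(d['msega_frail_n'] / self.n)})"
        )
        lines.append("")
        for title, summaries in (
            ("Item accuracy vs mSEGA frailty", self.item_vs_sega),
            ("Item comparison vs ZFS frailty", self.item_vs_zfs),
        ):
            if not summaries:
                lines.append(f"{title}: [degenerate stratum, section skipped]")
                continue
            lines.append(title)
            lines.append(f"  {'item':<26} {'Se':>5} {'Sp':>5} {'PPV':>5} {'NPV':>5} "
                         f"{'RR':>6}  p (method)")
            for name, s in summaries.items():
                rr = ("undef" if s.risk_ratio is None
                      else "inf" if math.isinf(s.risk_ratio) else f"{s.risk_ratio:.2f}")
                lines.append(
                    f"  {name:<26} {pct(s.sensitivity):>5} {pct(s.specificity):>5} "
                    f"{pct(s.ppv):>5} {pct(s.npv):>5} {rr:>6}  "
                    f"{s.p_value:.3f} ({s.p_method})"
                )
            lines.append("")
        if self.curve is not None:
            lines.append("ROC cut-point table (positive iff score >= c)")
            lines.append(f"  {'c':>2} {'1-Sp':>7} {'Se':>5} {'Sp':>5} {'Youden':>7} "
                         f"{'PPV':>5} {'NPV':>5}")
            for r in self.curve.rows:
                lines.append(
                    f"  {r.cutpoint:>2} {r.one_minus_sp:>7.4f} {pct(r.se):>5} "
                    f"{pct(r.sp):>5} {pct(r.youden):>7} {pct(r.ppv):>5} {pct(r.npv):>5}"
                )
            lines.append(f"  AUC = {self.auc:.5f}; optimal cutpoint (max Youden) = "
                         f">={self.optimal_cutpoint}")
        else:
            lines.append("ROC analysis: [degenerate stratum, section skipped]")
        lines.append("")
        if self.totals_r is not None:
            ci = self.totals_ci
            ci_txt = f" [95% CI {ci[0]:.2f}; {ci[1]:.2f}]" if ci else ""
            lines.append(f"Cross-scale total-score Pearson r = {self.totals_r:.2f}{ci_txt}")
        else:
            lines.append("Cross-scale correlation: undefined (constant totals)")
        if self.degenerate:
            lines.append("")
            lines.append(f"WARNING: degenerate sections: {', '.join(self.degenerate_sections)}")
        return "\n".join(lines) + "\n"


def validation_report(
    cohort: pd.DataFrame | list[Mapping[str, object]],
    zfs_threshold: int = 3,
    msega_cutoff: int = 8,
) -> ValidationReport:
    """Run the full validation pipeline on a dual-scale cohort.

    A degenerate frailty stratum (no frail or no non-frail patients under the
    mSEGA criterion) skips the per-item accuracy and ROC sections, flags the
    report, and sets a distinct exit status instead of aborting.
    """
    if isinstance(cohort, pd.DataFrame):
        records = cohort.to_dict("records")
    else:
        records = list(cohort)
    scores = cohort_scores(records, zfs_threshold=zfs_threshold)
    n = len(scores)
    if n == 0:
        raise InvalidResponseError("cohort contains no complete records")
    msega_frail = scores.msega_total > msega_cutoff

    zfs_classes = {
        "robust": int(np.sum(scores.zfs_score == 0)),
        "pre_frail": int(np.sum((scores.zfs_score >= 1) & (scores.zfs_score < zfs_threshold))),
        "frail": int(np.sum(scores.zfs_score >= zfs_threshold)),
    }
    descriptives: dict[str, object] = {
        "zfs_mean": float(scores.zfs_score.mean()),
        "zfs_sd": float(scores.zfs_score.std(ddof=1)) if n > 1 else 0.0,
        "zfs_classes": zfs_classes,
        "zfs_screen_positive": int(np.sum(scores.zfs_score >= 1)),
        "msega_mean": float(scores.msega_total.mean()),
        "msega_sd": float(scores.msega_total.std(ddof=1)) if n > 1 else 0.0,
        "msega_frail_n": int(msega_frail.sum()),
    }

    degenerate_sections: list[str] = []
    item_vs_sega: dict[str, DiagnosticSummary] = {}
    item_vs_zfs: dict[str, DiagnosticSummary] = {}
    curve = None
    area = None
    best = None

    item_vectors = {
        name: np.array([int(_get_item(r, name)) for r in records], dtype=bool)
        for name in ZFS_ITEMS
    }
    if 0 < int(msega_frail.sum()) < n:
        for name, vec in item_vectors.items():
            item_vs_sega[name] = diag_metrics(crosstab(vec, msega_frail))
        dist = ScoreDistribution.from_scores(scores.zfs_score, msega_frail)
        curve = cutpoint_table(dist)
        area = auc(dist)
        best = optimal_cutpoint(curve)
    else:
        degenerate_sections += ["item_vs_sega", "roc"]
    if 0 < int(scores.zfs_frail.sum()) < n:
        for name, vec in item_vectors.items():
            item_vs_zfs[name] = diag_metrics(crosstab(vec, scores.zfs_frail))
    else:
        degenerate_sections.append("item_vs_zfs")

    totals_r = pearson_r(scores.zfs_score, scores.msega_total) if n >= 3 else math.nan
    totals_ci = None
    if math.isnan(totals_r):
        totals_r_out = None
        degenerate_sections.append("totals_correlation")
    else:
        totals_r_out = totals_r
        if abs(totals_r) < 1:
            totals_ci = pearson_ci(totals_r, n)

    return ValidationReport(
        n=n,
        zfs_threshold=zfs_threshold,
        msega_cutoff=msega_cutoff,
        item_vs_sega=item_vs_sega,
        item_vs_zfs=item_vs_zfs,
        curve=curve,
        auc=area,
        optimal_cutpoint=best,
        totals_r=totals_r_out,
        totals_ci=totals_ci,
        descriptives=descriptives,
        degenerate=bool(degenerate_sections),
        degenerate_sections=tuple(degenerate_sections),
        metadata={
            "version": _version,
            "skipped_records": list(scores.skipped),
        },
    )


def _get_item(record: Mapping[str, object], name: str) -> object:
    if f"zfs_{name}" in record:
        return record[f"zfs_{name}"]
    return record[name]
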