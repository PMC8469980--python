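"""Published summary tables from the ZFS ambulatory validation cohort (n = 102).

The original validation study of the Zulfiqar Frailty Scale enrolled 102
ambulatory patients aged 65+ and scored each on the ZFS and on mSEGA grid A.
The raw per-patient data were never deposited; what survives in print are
summary tables: per-item 2x2 contingencies against SEGA-defined frailty,
the cumulative ROC cut-point table, item prevalences, classification counts,
and demographic moments.  This module embeds those printed values verbatim
(decimal commas normalised to dots) as code constants, each carrying a
provenance label, so the whole validation analysis can be reproduced
hermetically and every constant audited against its source.

``reconstructed_cohort`` expands the published score-by-frailty distribution
back into 102 patient records.  ZFS totals and SEGA frailty flags in that
cohort are exact; the item-level response patterns and mSEGA item codes are
synthetic placeholders chosen only to produce the right totals, and must not
be used for item-level analyses (use the contingency tables for those).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diagnostics import ContingencyTable2x2
from .roc import ScoreDistribution, reconstruct_distribution
from .scales import MSEGA_ITEMS, ZFS_ITEMS

__all__ = [
    "PaperFixture",
    "item_vs_sega_tables",
    "zfs_internal_tables",
    "roc_cumulative_rows",
    "item_prevalences",
    "classification_counts",
    "cohort_demographics",
    "reconstructed_distribution",
    "reconstructed_cohort",
    "COHORT_N",
    "SEGA_FRAIL_N",
]

COHORT_N = 102      #: validation cohort size
SEGA_FRAIL_N = 20   #: patients with mSEGA grid A total > 8 (prevalence 19.6%)


@dataclass(frozen=True)
class PaperFixture:
    """A published table embedded as a typed constant, with provenance."""

    name: str
    payload: object
    provenance: str


# Per-item 2x2 tables against SEGA-defined frailty (condition = mSEGA total > 8).
# (tp, fp, fn, tn): tp = item yes & frail, fp = item yes & not frail, etc.
_ITEM_VS_SEGA: dict[str, tuple[int, int, int, int]] = {
    "weight_loss_ge5pct_6mo": (4, 2, 16, 80),
    "monopodal_stance_lt5s": (17, 38, 3, 44),
    "lives_alone": (13, 32, 7, 50),
    "home_aid_present": (16, 9, 4, 73),
    "memory_complaint": (11, 24, 9, 58),
    "polypharmacy_ge5_classes": (15, 31, 5, 51),
}

# Per-item 2x2 tables against the ZFS's own frailty classification (score >= 3,
# 36 frail vs 66 not), from the scale-internal item comparison table.
_ITEM_VS_ZFS: dict[str, tuple[int, int, int, int]] = {
    "weight_loss_ge5pct_6mo": (4, 2, 32, 64),
    "monopodal_stance_lt5s": (31, 24, 5, 42),
    "lives_alone": (26, 19, 10, 47),
    "home_aid_present": (22, 3, 14, 63),
    "memory_complaint": (19, 16, 17, 50),
    "polypharmacy_ge5_classes": (27, 19, 9, 47),
}

# Cumulative ROC rows (cutpoint c meaning "score >= c", se, 1-sp).  The
# published table labels rows ">k"; with the ">= k" reading, row c=1 yields 87
# screen-positives and row c=3 yields 36 frail, both matching the printed
# classification counts — the literal ">" reading matches neither.
_ROC_ROWS: tuple[tuple[int, float, float], ...] = (
    (1, 1.00, 0.8171),
    (2, 1.00, 0.6098),
    (3, 1.00, 0.1951),
    (4, 0.65, 0.0488),
    (5, 0.15, 0.0122),
)

# Item "yes" counts over the 102 patients.
_ITEM_PREVALENCE_COUNTS: dict[str, int] = {
    "weight_loss_ge5pct_6mo": 6,
    "monopodal_stance_lt5s": 55,
    "lives_alone": 45,
    "home_aid_present": 25,
    "memory_complaint": 35,
    "polypharmacy_ge5_classes": 46,
}

_ZFS_CLASSIFICATION: dict[str, int] = {"not_frail": 15, "pre_frail": 51, "frail": 36}
_ZFS_SCREEN_POSITIVE = 87  # score >= 1, printed as "frailty according to ZFS: yes"
_ZFS_SCORE_MEAN_SD = (2.1, 1.35)

_SEGA_CLASSIFICATION: dict[str, int] = {"not_frail": 82, "frail": 16, "very_frail": 4}
_SEGA_TOTAL_MEAN_SD = (5.61, 3.11)

# Demographic moments: mean, sd (or counts for sex).  The printed IADL scale
# annotation ("/4") is inconsistent with its mean of 7.04 (IADL is
# conventionally scored out of 8); values are stored exactly as printed.
_DEMOGRAPHICS: dict[str, tuple[float, float]] = {
    "age": (76.0, 8.0),
    "weight_kg": (74.0, 15.0),
    "height_cm": (166.0, 9.0),
    "n_medications": (4.3, 3.0),
    "charlson": (4.11, 1.81),
    "adl": (5.83, 0.35),
    "iadl": (7.04, 1.68),
}
_SEX_COUNTS = {"female": 55, "male": 47}


def item_vs_sega_tables() -> dict[str, ContingencyTable2x2]:
    """The six per-item 2x2 tables against SEGA-defined frailty (20 frail / 82 not)."""
    return {k: ContingencyTable2x2(*v) for k, v in _ITEM_VS_SEGA.items()}


def zfs_internal_tables() -> dict[str, ContingencyTable2x2]:
    """Per-item 2x2 tables against the ZFS's own frail class (36 frail / 66 not)."""
    return {k: ContingencyTable2x2(*v) for k, v in _ITEM_VS_ZFS.items()}


def roc_cumulative_rows() -> tuple[tuple[int, float, float], ...]:
    """Published cumulative ROC rows as (cutpoint, se, 1-sp), c = 1..5."""
    return _ROC_ROWS


def item_prevalences() -> dict[str, int]:
    """Item 'yes' counts over the 102-patient cohort."""
    return dict(_ITEM_PREVALENCE_COUNTS)


def classification_counts() -> dict[str, dict[str, int]]:
    """ZFS and mSEGA classification counts, plus the ZFS screen-positive count."""
    return {
        "zfs": dict(_ZFS_CLASSIFICATION),
        "zfs_screen_positive": {"score_ge1": _ZFS_SCREEN_POSITIVE},
        "msega": dict(_SEGA_CLASSIFICATION),
    }


def score_summaries() -> dict[str, tuple[float, float]]:
    """Printed mean/sd of the two scale totals."""
    return {"zfs": _ZFS_SCORE_MEAN_SD, "msega": _SEGA_TOTAL_MEAN_SD}


def cohort_demographics() -> dict[str, tuple[float, float]]:
    """Demographic moments (mean, sd) of the validation cohort."""
    return dict(_DEMOGRAPHICS)


def sex_counts() -> dict[str, int]:
    """Cohort sex split."""
    return dict(_SEX_COUNTS)


def all_fixtures() -> tuple[PaperFixture, ...]:
    """Every embedded constant, labelled, for auditing and text export."""
    return (
        PaperFixture("item_vs_sega_tables", _ITEM_VS_SEGA,
                     "validation cohort: per-item 2x2 vs SEGA frailty"),
        PaperFixture("zfs_internal_tables", _ITEM_VS_ZFS,
                     "validation cohort: per-item 2x2 vs ZFS frailty"),
        PaperFixture("roc_cumulative_rows", _ROC_ROWS,
                     "validation cohort: cumulative ROC cut-point table"),
        PaperFixture("item_prevalences", _ITEM_PREVALENCE_COUNTS,
                     "validation cohort: item yes-counts"),
        PaperFixture("zfs_classification", _ZFS_CLASSIFICATION,
                     "validation cohort: ZFS class counts"),
        PaperFixture("sega_classification", _SEGA_CLASSIFICATION,
                     "validation cohort: mSEGA class counts"),
        PaperFixture("score_summaries", {"zfs": _ZFS_SCORE_MEAN_SD, "msega": _SEGA_TOTAL_MEAN_SD},
                     "validation cohort: scale total mean (sd)"),
        PaperFixture("demographics", _DEMOGRAPHICS,
                     "validation cohort: demographic moments"),
        PaperFixture("sex_counts", _SEX_COUNTS, "validation cohort: sex split"),
    )


def expand_table(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 2x2 table into paired (test, condition) indicator vectors."""
    test = np.repeat([True, True, False, False], [table.tp, table.fp, table.fn, table.tn])
    cond = np.repeat([True, False, True, False], [table.tp, table.fp, table.fn, table.tn])
    return test, cond


def reconstructed_distribution() -> ScoreDistribution:
    """ZFS score-by-SEGA-frailty distribution recovered from the cumulative ROC rows.

    Scores >= 5 are collapsed onto 5 (the published table stops there); the
    collapse is validated elsewhere by recovering the printed cohort mean and
    SD of the ZFS total.
    """
    return reconstruct_distribution(_ROC_ROWS, n_pos=SEGA_FRAIL_N, n_neg=COHORT_N - SEGA_FRAIL_N)


def _zfs_pattern(score: int) -> dict[str, int]:
    return {item: int(i < score) for i, item in enumerate(ZFS_ITEMS)}


def _msega_pattern(total: int) -> dict[str, int]:
    values = []
    remaining = total
    for _ in MSEGA_ITEMS:
        take = min(2, remaining)
        values.append(take)
        remaining -= take
    if remaining:
        raise ValueError(f"mSEGA total {total} exceeds the scale maximum")
    return dict(zip(MSEGA_ITEMS, values))


def reconstructed_cohort(
    msega_total_frail: int = 10, msega_total_not_frail: int = 5
) -> pd.DataFrame:
    """102 synthetic patient records matching the published score distribution.

    ZFS totals and SEGA frailty status are exact (20 frail, 82 not frail; 36
    ZFS-frail).  Item-level patterns are synthetic: a ZFS score of s is coded
    as the first s items 'yes', and mSEGA items encode a fixed total per
    frailty stratum (defaults near the printed stratum means).  Use only for
    total-score analyses.
    """
    if not msega_total_frail > 8 >= msega_total_not_frail:
        raise ValueError("stratum totals must straddle the mSEGA frailty cut-off of 8")
    dist = reconstructed_distribution()
    records = []
    pid = 0
    for frail, counts, total in (
        (True, dist.pos_counts, msega_total_frail),
        (False, dist.neg_counts, msega_total_not_frail),
    ):
        for score, count in enumerate(counts):
            for _ in range(count):
                record: dict[str, object] = {"patient_id": f"p{pid:03d}"}
                record.update({f"zfs_{k}": v for k, v in _zfs_pattern(score).items()})
                record.update({f"msega_{k}": v for k, v in _msega_pattern(total).items()})
                records.append(record)
                pid += 1
    return pd.DataFrame(records)
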