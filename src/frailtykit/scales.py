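"""Scoring and classification for the ZFS and the modified SEGA grid A.

The Zulfiqar Frailty Scale (ZFS) is a six-item binary screening questionnaire
for frailty in ambulatory patients aged 65 and over.  Each "yes" scores one
point; 0 is robust, 1-2 pre-frail, and >= 3 (the default threshold) frail.

The modified SEGA grid A (Short Emergency Geriatric Assessment, part A) is a
13-item geriatric assessment, each item coded 0/1/2 by the clinician, total
out of 26.  Totals <= 8 are not frail, 9-11 frail, > 11 very frail; the
binary frailty criterion used for validating screening scales is total > 8.

This module consumes already-coded responses (0/1 for ZFS, 0/1/2 for mSEGA);
the clinical rubric that assigns those codes is out of scope.  Scoring is
pure and deterministic; missing answers are rejected, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical ZFS item order (also the serialization order of ``zfs_*`` columns).
ZFS_ITEMS: tuple[str, ...] = (
    "weight_loss_ge5pct_6mo",
    "monopodal_stance_lt5s",
    "lives_alone",
    "home_aid_present",
    "memory_complaint",
    "polypharmacy_ge5_classes",
)

#: Canonical mSEGA grid A item order, matching the printed grid.
MSEGA_ITEMS: tuple[str, ...] = (
    "age",
    "provenance",
    "medications",
    "mood",
    "perception_of_health",
    "fall_6_months",
    "nutrition",
    "sicknesses",
    "iadl",
    "mobility",
    "continence",
    "meals",
    "cognition",
)

ZFS_MAX = len(ZFS_ITEMS)          # 6
MSEGA_MAX = 2 * len(MSEGA_ITEMS)  # 26

#: mSEGA category boundaries: <=8 not frail, 9-11 frail, >11 very frail.
MSEGA_FRAILTY_CUTOFF = 8
MSEGA_VERY_FRAIL_CUTOFF = 11

#: Default ZFS frailty threshold: frail iff score >= 3.
ZFS_DEFAULT_THRESHOLD = 3


class IncompleteResponseError(ValueError):
    """A required item is missing from a response set."""


class InvalidResponseError(ValueError):
    """An item carries a value outside its allowed alphabet."""


@dataclass(frozen=True)
class ZfsResult:
    """Outcome of scoring one patient on the ZFS."""

    score: int
    category: str  # robust | pre_frail | frail
    frail_flag: bool


@dataclass(frozen=True)
class MsegaResult:
    """Outcome of scoring one patient on mSEGA grid A."""

    total: int
    category: str  # not_frail | frail | very_frail
    frail_flag: bool


def _coerce_binary(item: str, value: object) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise IncompleteResponseError(f"missing answer for ZFS item {item!r}")
    if isinstance(value, str):
        token = value.strip().lower()
        if token in {"1", "yes", "y", "oui", "true"}:
            return 1
        if token in {"0", "no", "n", "non", "false"}:
            return 0
        raise InvalidResponseError(f"ZFS item {item!r}: cannot read {value!r} as yes/no")
    if isinstance(value, (bool, np.bool_)):
        return int(value)
    iv = int(value)
    if iv != value or iv not in (0, 1):
        raise InvalidResponseError(f"ZFS item {item!r}: value {value!r} not in {{0, 1}}")
    return iv


def _coerce_ordinal(item: str, value: object) -> int:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        raise IncompleteResponseError(f"missing answer for mSEGA item {item!r}")
    if isinstance(value, str):
        try:
            iv = int(value.strip())
        except ValueError as exc:
            raise InvalidResponseError(f"mSEGA item {item!r}: value {value!r} is not an integer") from exc
    else:
        try:
            iv = int(value)
        except (TypeError, ValueError) as exc:
            raise InvalidResponseError(f"mSEGA item {item!r}: value {value!r} is not an integer") from exc
        if iv != value:
            raise InvalidResponseError(f"mSEGA item {item!r}: value {value!r} is not an integer")
    if iv not in (0, 1, 2):
        raise InvalidResponseError(f"mSEGA item {item!r}: value {value!r} not in {{0, 1, 2}}")
    return iv


def zfs_category(score: int, threshold: int = ZFS_DEFAULT_THRESHOLD) -> str:
    """Classify an integer ZFS score: 0 robust, below-threshold pre-frail, else frail."""
    if score == 0:
        return "robust"
    return "frail" if score >= threshold else "pre_frail"


def msega_category(total: int) -> str:
    """Classify an mSEGA grid A total: <=8 not frail, 9-11 frail, >11 very frail."""
    if total > MSEGA_VERY_FRAIL_CUTOFF:
        return "very_frail"
    return "frail" if total > MSEGA_FRAILTY_CUTOFF else "not_frail"


def score_zfs(responses: Mapping[str, object], threshold: int = ZFS_DEFAULT_THRESHOLD) -> ZfsResult:
    """Score one patient on the ZFS.

    Parameters
    ----------
    responses
        Mapping with one entry per item in :data:`ZFS_ITEMS`; values may be
        0/1 integers, booleans, or yes/no (oui/non) strings.
    threshold
        Minimum score classified as frail (default 3, the scale's published
        cut-off; exposed so threshold sweeps can reuse the classifier).

    Raises
    ------
    IncompleteResponseError
        If any of the six items is absent or missing-valued (no imputation).
    InvalidResponseError
        If a value falls outside the binary alphabet.
    """
    if not 1 <= threshold <= ZFS_MAX:
        raise ValueError(f"threshold must be in [1, {ZFS_MAX}], got {threshold}")
    values = []
    for item in ZFS_ITEMS:
        if item not in responses:
            raise IncompleteResponseError(f"missing answer for ZFS item {item!r}")
        values.append(_coerce_binary(item, responses[item]))
    score = sum(values)
    category = zfs_category(score, threshold)
    return ZfsResult(score=score, category=category, frail_flag=category == "frail")


def score_msega(responses: Mapping[str, object]) -> MsegaResult:
    """Score one patient on mSEGA grid A (sum of the thirteen 0/1/2 items)."""
    values = []
    for item in MSEGA_ITEMS:
        if item not in responses:
            raise IncompleteResponseError(f"missing answer for mSEGA item {item!r}")
        values.append(_coerce_ordinal(item, responses[item]))
    total = sum(values)
    category = msega_category(total)
    return MsegaResult(total=total, category=category, frail_flag=total > MSEGA_FRAILTY_CUTOFF)


@dataclass(frozen=True)
class CohortScores:
    """Per-patient score vectors for a dual-scale cohort, in input order."""

    zfs_score: np.ndarray
    zfs_frail: np.ndarray
    msega_total: np.ndarray
    msega_frail: np.ndarray
    skipped: tuple[object, ...] = ()

    def __len__(self) -> int:
        return len(self.zfs_score)


def cohort_scores(
    cohort: Iterable[Mapping[str, object]],
    zfs_threshold: int = ZFS_DEFAULT_THRESHOLD,
    strict: bool = True,
) -> CohortScores:
    """Score every patient in a cohort on both scales.

    Each record must carry all six ZFS items and all thirteen mSEGA items
    (optionally prefixed ``zfs_`` / ``msega_`` as in the file format).  In
    strict mode an incomplete record aborts scoring; otherwise it is skipped
    and its identifier logged and returned in ``skipped``.
    """
    zfs_score: list[int] = []
    zfs_frail: list[bool] = []
    msega_total: list[int] = []
    msega_frail: list[bool] = []
    skipped: list[object] = []
    for i, record in enumerate(cohort):
        flat = _strip_prefixes(record)
        try:
            z = score_zfs(flat, threshold=zfs_threshold)
            m = score_msega(flat)
        except (IncompleteResponseError, InvalidResponseError):
            if strict:
                raise
            ident = record.get("patient_id", i)
            logger.warning("skipping incomplete record %r", ident)
            skipped.append(ident)
            continue
        zfs_score.append(z.score)
        zfs_frail.append(z.frail_flag)
        msega_total.append(m.total)
        msega_frail.append(m.frail_flag)
    if skipped:
        logger.warning("skipped %d incomplete records", len(skipped))
    return CohortScores(
        zfs_score=np.asarray(zfs_score, dtype=int),
        zfs_frail=np.asarray(zfs_frail, dtype=bool),
        msega_total=np.asarray(msega_total, dtype=int),
        msega_frail=np.asarray(msega_frail, dtype=bool),
        skipped=tuple(skipped),
    )


def _strip_prefixes(record: Mapping[str, object]) -> dict[str, object]:
    """Accept both bare item names and zfs_/msega_-prefixed column names."""
    flat: dict[str, object] = {}
    for key, value in record.items():
        if key.startswith("zfs_"):
            flat.setdefault(key[4:], value)
        elif key.startswith("msega_"):
            flat.setdefault(key[6:], value)
        else:
            flat.setdefault(key, value)
    return flat
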