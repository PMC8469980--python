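"""Pearson correlations between scale items and totals.

Binary items enter as 0/1 numerics, so an item-item correlation is the phi
coefficient; ordinal mSEGA items enter as 0/1/2 numerics.  Correlations that
are undefined because an input is constant are returned as NaN — an explicit
sentinel, never silently 0, so a constant column cannot masquerade as
independence.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scales import MSEGA_ITEMS, ZFS_ITEMS, _strip_prefixes

__all__ = ["pearson_r", "pearson_ci", "item_matrix"]


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; NaN when either vector is constant.

    On 0/1 vectors this equals the phi coefficient
    (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)) of the induced 2x2 table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D of equal length, got {x.shape}, {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a correlation coefficient.

    tanh(atanh(r) +/- z * (n - 3)^(-1/2)); degenerate (|r| = 1) input is
    rejected because the transform diverges there.
    """
    if not -1 < r < 1:
        raise ValueError(f"|r| must be < 1 for the Fisher z interval, got r={r}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if not 0 <= level < 1:
        raise ValueError(f"level must be in [0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2)
    half = z / math.sqrt(n - 3)
    centre = math.atanh(r)
    return (math.tanh(centre - half), math.tanh(centre + half))


def item_matrix(cohort: Iterable[Mapping[str, object]]) -> pd.DataFrame:
    """Pearson correlation matrix between ZFS items (rows) and mSEGA items (columns).

    Constant columns yield NaN entries; the matrix is still returned.  The
    correlation between the two scale totals, with its Fisher-z 95% CI, is
    attached as ``DataFrame.attrs['totals_r']`` / ``attrs['totals_ci']``.
    """
    records = [_strip_prefixes(r) for r in cohort]
    if not records:
        raise ValueError("cohort is empty")
    zfs = pd.DataFrame([[float(r[i]) for i in ZFS_ITEMS] for r in records], columns=ZFS_ITEMS)
    msega = pd.DataFrame([[float(r[i]) for i in MSEGA_ITEMS] for r in records], columns=MSEGA_ITEMS)

    values = np.full((len(ZFS_ITEMS), len(MSEGA_ITEMS)), np.nan)
    for i, zi in enumerate(ZFS_ITEMS):
        for j, mj in enumerate(MSEGA_ITEMS):
            values[i, j] = pearson_r(zfs[zi].to_numpy(), msega[mj].to_numpy())
    matrix = pd.DataFrame(values, index=list(ZFS_ITEMS), columns=list(MSEGA_ITEMS))

    totals_r = pearson_r(zfs.sum(axis=1).to_numpy(), msega.sum(axis=1).to_numpy())
    matrix.attrs["totals_r"] = totals_r
    if not math.isnan(totals_r) and abs(totals_r) < 1 and len(records) >= 4:
        matrix.attrs["totals_ci"] = pearson_ci(totals_r, len(records))
    else:
        matrix.attrs["totals_ci"] = None
    return matrix
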