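"""Overlap metrics, cohort aggregation and the paired method comparison.

The overlap coefficient (OC) is Szymkiewicz–Simpson:
``|A n B| / min(|A|, |B|)`` — 1 when the smaller mask is fully enclosed by
the larger, 0 when they are disjoint.  Dice is the standard symmetric
``2|A n B| / (|A| + |B|)``, so OC >= Dice wherever both are defined.

Undefined values (an empty mask where the metric needs a nonempty one)
are reported as None / NaN, never silently as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ntms import CLASSES
from .volumes import BinaryMask, require_same_grid

logger = logging.getLogger(__name__)

__all__ = [
    "overlap_coefficient",
    "dice",
    "ConcordanceTable",
    "cohort_mean_oc",
    "wilcoxon_signed_rank",
    "oc_ordering_check",
]


def overlap_coefficient(a: BinaryMask, b: BinaryMask) -> float | None:
    """Szymkiewicz–Simpson overlap: |A n B| / min(|A|, |B|).

    Returns None (undefined) when either mask is empty.  Symmetric.  The
    second argument is conventionally the response mask, expected to be
    the smaller set; a warning is logged when that expectation is
    violated.
    """
    require_same_grid(a, b, "overlap coefficient")
    na, nb = a.foreground_count, b.foreground_count
    if min(na, nb) == 0:
        return None
    if nb > na:
        logger.warning(
            "overlap_coefficient: second mask (|B|=%d) is larger than the first "
            "(|A|=%d); the smaller-set convention is violated",
            nb,
            na,
        )
    inter = int(np.count_nonzero(a.data.astype(bool) & b.data.astype(bool)))
    return inter / min(na, nb)


def dice(a: BinaryMask, b: BinaryMask) -> float | None:
    """Dice coefficient 2|A n B| / (|A| + |B|); None when both masks are empty."""
    require_same_grid(a, b, "dice")
    na, nb = a.foreground_count, b.foreground_count
    if na + nb == 0:
        return None
    inter = int(np.count_nonzero(a.data.astype(bool) & b.data.astype(bool)))
    return 2.0 * inter / (na + nb)


@dataclass
class ConcordanceTable:
    """Per-subject overlap values across methods and response classes.

    ``frame`` has one row per (subject_id, method) with one ``oc_<klass>``
    column per response class, plus a per-subject ``dice`` frame between
    method pairs.
    """

    frame: pd.DataFrame
    dice_frame: pd.DataFrame | None = None

    OC_COLUMNS = {k: f"oc[{k}]" for k in CLASSES}

    def __post_init__(self) -> None:
        needed = {"subject_id", "method", *self.OC_COLUMNS.values()}
        missing = needed - set(self.frame.columns)
        if missing:
            raise ValueError(f"concordance frame is missing columns: {sorted(missing)}")
        if self.frame.duplicated(["subject_id", "method"]).any():
            raise ValueError("one row per (subject_id, method) required")
        for col in self.OC_COLUMNS.values():
            vals = self.frame[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} values must lie in [0, 1]")

    def column(self, method: str, klass: str) -> pd.Series:
        sel = self.frame[self.frame["method"] == method]
        return sel.set_index("subject_id")[self.OC_COLUMNS[klass]]


def cohort_mean_oc(
    table: ConcordanceTable, method: str, klass: str, ddof: int = 1
) -> tuple[float, float]:
    """Cohort mean and std of OC for one method/class over defined values.

    ``ddof=1`` (sample std) matches how cohort spreads are conventionally
    reported alongside the mean.
    """
    vals = table.column(method, klass).dropna()
    if len(vals) == 0:
        raise ValueError(f"no defined OC values for method={method!r} klass={klass!r}")
    std = 0.0 if len(vals) < 2 else float(vals.std(ddof=ddof))
    return float(vals.mean()), std


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's classic rule); ties among
    |differences| get average ranks.  The exact null distribution is used
    for n <= 25 with no ties, otherwise the normal approximation with tie
    correction.  Fewer than 5 nonzero differences is an error: the test
    would be underpowered and misleading.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples must have equal length, got {x.shape} vs {y.shape}")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n < 5:
        raise ValueError(
            f"only {n} nonzero paired differences; at least 5 are required for a "
            "meaningful signed-rank test"
        )
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def oc_ordering_check(
    oc_pos_in: float, oc_pos_out: float, oc_neg_out: float, tol: float = 1e-9
) -> bool:
    """True when OC(+M1+) >= OC(-M1+) >= OC(-M1-) within ``tol``.

    Ties (e.g. both outside-classes at 0) are allowed.
    """
    for v in (oc_pos_in, oc_pos_out, oc_neg_out):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError("all three class OC values must be defined")
    return oc_pos_in >= oc_pos_out - tol and oc_pos_out >= oc_neg_out - tol
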