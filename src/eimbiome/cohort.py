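"""Enrollment filtering, group-size bookkeeping and 2x2 contingency tests.

The enrolled cohort contains participants whose EIM status was never
confirmed by a specialist; those are excluded before any analysis.
Group composition (e.g. sex by phenotype) is compared with Fisher's
exact test or the Pearson chi-square, both delegated to scipy.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import scipy.stats

from .synthetic import CohortRecord

__all__ = [
    "apply_enrollment_filter",
    "group_sizes",
    "fisher_exact",
    "chi_square",
]


def apply_enrollment_filter(records: Sequence[CohortRecord]) -> list[CohortRecord]:
    """Drop participants whose EIM diagnosis was never confirmed."""
    return [r for r in records if r.eim_status != "unconfirmed"]


def group_sizes(records: Sequence[CohortRecord]) -> dict[tuple[str, str], int]:
    """Counts per (group, subtype) cell plus margins.

    Group is ``EIM`` for confirmed-EIM records and ``C`` otherwise;
    margins use subtype ``"all"`` and group ``"all"``.
    """
    cells: Counter = Counter()
    for r in records:
        if r.eim_status == "unconfirmed":
            raise ValueError("apply the enrollment filter before counting groups")
        if r.subtype not in ("CD", "UC"):
            raise ValueError(f"record {r.participant_id!r} missing subtype")
        group = "EIM" if r.eim_status == "confirmed" else "C"
        cells[(group, r.subtype)] += 1
        cells[(group, "all")] += 1
        cells[("all", r.subtype)] += 1
        cells[("all", "all")] += 1
    for group in ("EIM", "C", "all"):
        for subtype in ("CD", "UC", "all"):
            cells.setdefault((group, subtype), 0)
    return dict(cells)


def _as_table(table) -> np.ndarray:
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(arr < 0) or arr.sum() == 0:
        raise ValueError("cells must be non-negative with a positive total")
    return arr


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    p sums the hypergeometric probabilities of all tables (at fixed
    margins) no more probable than the observed one.  The odds ratio is
    the sample ad/(bc), infinite when bc = 0.
    """
    arr = _as_table(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("degenerate margin: an all-zero row or column")
    a, b, c, d = arr.ravel()
    odds = np.inf if b * c == 0 else (a * d) / (b * c)
    res = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return float(odds), float(res.pvalue)


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (df=1) on a 2x2 table, no Yates correction by default."""
    arr = _as_table(table)
    expected = scipy.stats.contingency.expected_freq(arr)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count: use fisher_exact instead")
    stat, p, _, _ = scipy.stats.chi2_contingency(arr, correction=correction)
    return float(stat), float(p)
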