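"""Frequency tables of angle classes and the two group-comparison procedures.

Two tests are used on the binned elongation angles:

* Pearson's chi-square (no continuity correction) on the 2 x 4 contingency table
  of bin counts, comparing whole distributions between two groups;
* a two-sample "t-test between percents" comparing one bin's percentage between
  two groups: the classical pooled two-proportion statistic referred to a t
  distribution with ``n1 + n2 - 2`` degrees of freedom.

Printed summary tables report percentages and group sizes only; integer counts
are reconstructed by rounding ``pct * n / 100`` and a row whose rounded counts do
not sum to ``n`` is refused as irreconcilable rather than silently adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import DegeneratePoolError, IrreconcilableRowError
from .scoring import BIN_ORDER, AngleBin, AlignmentRecord

__all__ = [
    "FrequencyTable",
    "TestResult",
    "PairResult",
    "frequency_table",
    "counts_from_percentages",
    "chi_square_test",
    "t_test_between_percents",
    "compare_all",
    "ALPHA_SIGNIFICANCE",
]

ALPHA_SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class FrequencyTable:
    """Bin counts for one group (one region of one shape on one day).

    ``counts`` are ordered (RADIAL, PERIPHERAL, OBLIQUE_NEAR, OBLIQUE_FAR).
    """

    group_label: str
    day: int
    counts: Tuple[int, int, int, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def percents(self) -> Tuple[float, float, float, float]:
        return tuple(100.0 * c / self.n for c in self.counts)


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical comparison."""

    method: str                 # "chi_square" | "t_between_percents"
    statistic: float
    df: int
    p_two_sided: float
    warnings: Tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_two_sided < ALPHA_SIGNIFICANCE


def frequency_table(records: Iterable[AlignmentRecord], group_label: str, day: Optional[int] = None) -> FrequencyTable:
    """Tally alignment records into a four-bin frequency table."""
    records = list(records)
    if day is None:
        days = {r.day for r in records}
        day = days.pop() if len(days) == 1 else -1
    counts = tuple(sum(1 for r in records if r.bin is b) for b in BIN_ORDER)
    return FrequencyTable(group_label=group_label, day=day, counts=counts)


def counts_from_percentages(percents: Sequence[float], n: int) -> Tuple[int, ...]:
    """Invert printed percentages to integer bin counts.

    Each count is ``round(pct * n / 100)``; if the rounded counts do not sum to
    ``n`` the row is garbled and an :class:`IrreconcilableRowError` is raised —
    no silent largest-remainder fixing is attempted.
    """
    if n <= 0:
        raise ValueError(f"group size must be positive, got {n}")
    total = float(sum(percents))
    if abs(total - 100.0) > 0.2:
        raise IrreconcilableRowError(f"percentages sum to {total:.2f}, not 100 +/- 0.2")
    counts = tuple(int(round(p * n / 100.0)) for p in percents)
    if sum(counts) != n:
        raise IrreconcilableRowError(
            f"rounded counts {counts} sum to {sum(counts)}, expected n = {n}"
        )
    return counts


def chi_square_test(a: FrequencyTable, b: FrequencyTable) -> TestResult:
    """Pearson chi-square on the 2 x k contingency table of the two groups.

    No continuity correction.  Bins empty in both groups contribute no expected
    count; they are dropped with df reduced accordingly and a warning attached.
    """
    obs = np.array([a.counts, b.counts], dtype=float)
    warnings: tuple[str, ...] = ()
    keep = obs.sum(axis=0) > 0
    if not keep.all():
        dropped = [BIN_ORDER[i].value for i in np.flatnonzero(~keep)]
        warnings = (f"dropped zero-total bins: {', '.join(dropped)}",)
        obs = obs[:, keep]
    expected = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1  # (2-1) * (k-1)
    p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult("chi_square", stat, df, min(p, 1.0) if df > 0 else 1.0, warnings)


def t_test_between_percents(p1: float, n1: int, p2: float, n2: int) -> TestResult:
    """Two-sample t-test between percents.

    With pooled proportion ``pbar = (p1*n1 + p2*n2) / (100*(n1+n2))`` the
    statistic is ``t = (p1 - p2) / (100 * sqrt(pbar*(1-pbar)*(1/n1 + 1/n2)))``,
    referred two-sidedly to Student's t with ``n1 + n2 - 2`` df.  Identical to
    the pooled two-proportion z statistic except for the reference distribution.
    """
    for p in (p1, p2):
        if not (0.0 <= p <= 100.0):
            raise ValueError(f"percentage out of [0, 100]: {p}")
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    pbar = (p1 * n1 + p2 * n2) / (100.0 * (n1 + n2))
    if pbar in (0.0, 1.0):
        if p1 == p2:
            return TestResult("t_between_percents", 0.0, df, 1.0)
        raise DegeneratePoolError("pooled proportion is degenerate with unequal percentages")
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
    t = (p1 - p2) / (100.0 * se)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("t_between_percents", float(t), df, min(p, 1.0))


@dataclass(frozen=True)
class PairResult:
    """Chi-square plus per-bin t results for one planned pair of groups."""

    key_a: object
    key_b: object
    chi_square: TestResult
    t_by_bin: Mapping[AngleBin, TestResult]


def compare_all(
    groups: Mapping[object, FrequencyTable],
    plan: Iterable[Tuple[object, object]],
) -> list:
    """Run the planned pairwise comparisons.

    ``plan`` pairs keys of ``groups`` (e.g. piston vs control per day, day vs day
    within a region, shape vs shape per day).  Each pair yields one chi-square
    result on the full distributions and four t-between-percents results, one per
    bin.  Significance is read off each result at p < 0.05.
    """
    results = []
    for key_a, key_b in plan:
        for key in (key_a, key_b):
            if key not in groups:
                raise KeyError(f"unknown group label in comparison plan: {key!r}")
        a, b = groups[key_a], groups[key_b]
        pa, pb = a.percents, b.percents
        t_by_bin = {
            bin_: t_test_between_percents(pa[i], a.n, pb[i], b.n)
            for i, bin_ in enumerate(BIN_ORDER)
        }
        results.append(PairResult(key_a, key_b, chi_square_test(a, b), t_by_bin))
    return results
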