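"""Statistical layer for shell distributions and nucleus morphometry.

Covers the tests used in the study: Pearson chi-square homogeneity on
2×K shell-count tables, two-sided Mann-Whitney U for volume/flattening
(the morphometry samples are non-normal, as a Shapiro-Wilk gate
documents), exact reconstruction of integer counts from 2-decimal
percentage tables, and the myogenic fusion index FI = Nd/Nud.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from nucshell.errors import NucshellError


def round_half_up(x: np.ndarray | float, decimals: int = 2) -> np.ndarray:
    """Round with ties away from zero, the convention of printed tables.

    numpy rounds half to even; published percentage tables round 0.005 up,
    which matters when matching tables at 2 decimals exactly.
    """
    factor = 10.0**decimals
    x = np.asarray(x, float)
    return np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected_counts: np.ndarray  # 2 × K'
    warning_low_expected: bool  # any expected cell < 5
    dropped_columns: tuple[int, ...] = ()


@dataclass
class RankTestResult:
    u: float
    p_value: float
    n1: int
    n2: int
    alternative: str = "two-sided"
    method: str = "exact"


@dataclass
class CountReconstruction:
    percentages: np.ndarray
    n: int
    counts: np.ndarray
    exact: bool


def chi_square_homogeneity(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity on a 2×K count table.

    Expected counts come from the table margins; no continuity
    correction.  df = K' − 1 where K' excludes columns with zero total
    (dropped with a warning flag rather than failing, since sparse outer
    shells are common).  Cells with expected count < 5 set
    ``warning_low_expected`` but do not fail.
    """
    a = np.asarray(counts_a, int)
    b = np.asarray(counts_b, int)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D and the same length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if a.sum() == 0 or b.sum() == 0:
        raise NucshellError("chi-square requires both rows to have positive totals")
    col_totals = a + b
    keep = col_totals > 0
    dropped = tuple(int(i) for i in np.flatnonzero(~keep))
    table = np.vstack([a[keep], b[keep]])
    if table.shape[1] < 2:
        raise NucshellError("fewer than 2 informative shells; test undefined")
    statistic, p_value, df, expected = stats.chi2_contingency(
        table, correction=False
    )
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        expected_counts=expected,
        warning_low_expected=bool((expected < 5).any()),
        dropped_columns=dropped,
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float]
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the null distribution when n1 + n2 ≤ 12 and
    there are no ties; otherwise the normal approximation with mid-rank
    tie correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return RankTestResult(
        u=float(res.statistic),
        p_value=float(res.pvalue),
        n1=len(x),
        n2=len(y),
        method=method,
    )


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 ≤ n ≤ 5000).

    Used to document the normality gate before falling back to rank
    tests.  A constant sample is degenerate and raises.
    """
    x = np.asarray(x, float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise NucshellError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def reconstruct_counts(
    percentages: Sequence[float], n_max: int = 1000
) -> CountReconstruction:
    """Recover integer shell counts from a 2-decimal percentage row.

    Finds the smallest total n ≤ ``n_max`` such that the rounded counts
    c_k = round(n·p_k/100) sum to n and reproduce every percentage
    exactly at 2 decimals (half-up).  If no n matches, returns the
    least-squares best candidate with ``exact=False``.
    """
    p = np.asarray(percentages, float)
    if abs(p.sum() - 100.0) > 0.05:
        raise ValueError(f"percentages must sum to 100 ± 0.05 (got {p.sum():.4f})")
    best_n, best_counts, best_err = 0, None, np.inf
    for n in range(1, n_max + 1):
        counts = round_half_up(n * p / 100.0, 0).astype(int)
        if counts.sum() != n:
            continue
        achieved = round_half_up(100.0 * counts / n, 2)
        if np.array_equal(achieved, round_half_up(p, 2)):
            return CountReconstruction(p, n, counts, exact=True)
        err = float(((achieved - p) ** 2).sum())
        if err < best_err:
            best_n, best_counts, best_err = n, counts, err
    return CountReconstruction(
        p, best_n, best_counts if best_counts is not None else np.zeros_like(p, int),
        exact=False,
    )


def fusion_index(n_nuclei_in_myotubes: int, n_nuclei_undiff: int) -> float:
    """Fusion index FI = Nd / Nud.

    Nd = nuclei inside differentiated myotubes, Nud = nuclei in
    undifferentiated cells; measures myogenic differentiation efficiency.
    """
    if n_nuclei_undiff <= 0:
        raise ValueError("denominator (undifferentiated nuclei) must be > 0")
    if n_nuclei_in_myotubes < 0:
        raise ValueError("nucleus counts must be non-negative")
    return n_nuclei_in_myotubes / n_nuclei_undiff
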