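"""Mann–Whitney U test (exact and normal-approximation) and Gaussian summaries.

The exact two-sided p-value is computed by full enumeration of all
C(n1+n2, n1) group labelings of the pooled sample, using midranks so tied
data are handled without approximation.  For larger groups a normal
approximation with tie correction and continuity correction is used.
Two-sided p = min(1, 2·min(lower tail, upper tail)); significance
thresholds are always caller-supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

_EPS = 1e-9


@dataclass(frozen=True)
class TestResult:
    statistic: float          # U of the first group
    p_two_sided: float
    method: str               # "exact" | "normal_approximation"
    n1: int
    n2: int


@dataclass(frozen=True)
class SummaryResult:
    mean: float
    sd: float                 # NaN when undefined
    n: int
    sd_defined: bool


def _u_statistic(ranks: np.ndarray, idx1, n1: int) -> float:
    return float(ranks[list(idx1)].sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney(x, y, exact_limit: int = 8) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Exact by enumeration when both groups have at most ``exact_limit``
    observations (ties handled via midranks); otherwise a normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks, range(n1), n1)

    if max(n1, n2) <= exact_limit:
        n = n1 + n2
        total = math.comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            u = _u_statistic(ranks, idx, n1)
            if u <= u_obs + _EPS:
                le += 1
            if u >= u_obs - _EPS:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(u_obs, p, "exact", n1, n2)

    # normal approximation with tie correction
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return TestResult(u_obs, 1.0, "normal_approximation", n1, n2)
    diff = u_obs - mu
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0  # continuity, toward the mean
    z = (diff - cc) / math.sqrt(var)
    p = min(1.0, 2.0 * _norm_sf(abs(z)))
    return TestResult(u_obs, p, "normal_approximation", n1, n2)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def gaussian_summary(values) -> SummaryResult:
    """Sample mean and SD (n − 1 denominator); SD flagged undefined for n < 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if arr.size < 2:
        return SummaryResult(float(arr[0]), float("nan"), 1, False)
    return SummaryResult(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size), True)
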