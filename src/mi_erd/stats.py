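"""Nonparametric tests and distribution diagnostics used across the analysis.

All tests are two-sided at alpha = 0.05, with no multiple-testing correction
(a documented limitation of the analysis design). Mann-Whitney uses midranks
for ties; p-values come from exact enumeration for small tie-free samples and
from the tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "distribution_checks",
]

EXACT_MW_MAX_PRODUCT = 400  # exact enumeration when n_x * n_y <= this and tie-free
EXACT_WILCOXON_MAX_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple
    tie_corrected: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y, convention: str = "first") -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is U for ``x`` under the rank-sum convention
    (``U_x = R_x - n_x(n_x+1)/2``); ``convention="max"`` / ``"min"`` instead
    report max/min of (U_x, U_y), since published tables differ in which U
    they print. Exact null when ``n_x * n_y <= 400`` with no ties, otherwise
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = _has_ties(np.concatenate([x, y]))
    exact = (x.size * y.size <= EXACT_MW_MAX_PRODUCT) and not ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u_x = float(res.statistic)
    u_y = x.size * y.size - u_x
    stat = {"first": u_x, "max": max(u_x, u_y), "min": min(u_x, u_y)}[convention]
    return TestResult(
        statistic=stat, p_value=float(res.pvalue),
        method="mann-whitney-u-exact" if exact else "mann-whitney-u-normal",
        n=(x.size, y.size), tie_corrected=ties and not exact,
    )


def wilcoxon_signed_rank(x, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank test against ``mu0``.

    Zero differences are dropped (Wilcoxon's original rule). Exact null by
    sign enumeration for n <= 20 tie-free samples, else normal approximation
    with continuity correction.
    """
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero: test undefined")
    ties = _has_ties(np.abs(d))
    exact = d.size <= EXACT_WILCOXON_MAX_N and not ties
    res = sps.wilcoxon(
        d, alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
        zero_method="wilcox",
    )
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        method="wilcoxon-exact" if exact else "wilcoxon-normal",
        n=(d.size,), tie_corrected=ties and not exact,
    )


def distribution_checks(x, y) -> tuple[TestResult, TestResult]:
    """Normality (one-sample KS vs fitted normal, per pooled groups) and
    homoscedasticity (Brown-Forsythe Levene, median-centred) checks.

    The KS test uses each group's own fitted mean/SD and reports the least
    favourable (smallest) p over the two groups; estimating the parameters
    from the sample makes it anti-conservative (Lilliefors effect), which is
    accepted because the check only routes toward nonparametric tests.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")

    ks_stats = []
    for g in (x, y):
        sd = g.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance sample: KS normality check undefined")
        ks_stats.append(sps.kstest(g, "norm", args=(g.mean(), sd)))
    worst = min(ks_stats, key=lambda r: r.pvalue)
    ks = TestResult(statistic=float(worst.statistic), p_value=float(worst.pvalue),
                    method="ks-normality", n=(x.size, y.size))

    lev = sps.levene(x, y, center="median")
    levene = TestResult(statistic=float(lev.statistic), p_value=float(lev.pvalue),
                        method="levene-median", n=(x.size, y.size))
    return ks, levene
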