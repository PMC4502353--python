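"""Cross-subject statistics: normality gating, paired and one-sample t,
Wilcoxon signed-rank, and the Friedman test.

These are standard tests computed through scipy.stats behind a thin
contract layer: two-tailed throughout, alpha = 0.05, Shapiro-Wilk routing
between parametric and nonparametric branches, Wilcoxon zeros dropped
(Wilcoxon's original rule), Friedman with average ranks on ties. The
one-sample t from summary statistics exists so a printed "mean +- SD, n"
can be re-tested without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05
PARAMETRIC = "PARAMETRIC"
NONPARAMETRIC = "NONPARAMETRIC"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    df: float | None = None
    method: str = ""

    def as_dict(self) -> dict:
        out = {"statistic": self.statistic, "pvalue": self.pvalue, "method": self.method}
        if self.df is not None:
            out["df"] = self.df
        return out


def normality_gate(sample, alpha: float = ALPHA) -> str:
    """Shapiro-Wilk routing: PARAMETRIC unless normality is rejected."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    _, p = sps.shapiro(x)
    return PARAMETRIC if p >= alpha else NONPARAMETRIC


def paired_t(sample_a, sample_b) -> TestResult:
    """Paired two-tailed t-test on the within-subject differences."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult(0.0, 1.0, df=n - 1, method="paired t")
        raise ValueError("differences have zero variance; t is undefined")
    t, p = sps.ttest_rel(a, b)
    return TestResult(float(t), float(p), df=n - 1, method="paired t")


def one_sample_t_from_summary(
    mean: float, sd: float, n: int, mu0: float = 0.0
) -> TestResult:
    """Two-sided one-sample t from summary statistics (mean, SD, n)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), df=df, method="one-sample t (summary)")


def wilcoxon_signed_rank(sample_a, sample_b) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test; zero differences dropped.

    Exact null distribution for n <= 25 effective pairs when the absolute
    differences are untied; otherwise the normal approximation with
    continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    ranks_tied = len(np.unique(np.abs(d))) < n
    method = "approx" if (n > 25 or ranks_tied) else "exact"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      method=f"wilcoxon signed-rank ({method})")


def friedman(matrix) -> TestResult:
    """Friedman rank test across k related conditions (df = k - 1)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a subjects x conditions matrix, both >= 2")
    if m.shape[1] == 2:
        raise ValueError("Friedman needs at least 3 conditions")
    cols = [m[:, j] for j in range(m.shape[1])]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        return TestResult(0.0, 1.0, df=m.shape[1] - 1, method="friedman")
    chi2, p = sps.friedmanchisquare(*cols)
    return TestResult(float(chi2), float(p), df=m.shape[1] - 1, method="friedman")


def paired_location_test(sample_a, sample_b) -> TestResult:
    """Gate-routed paired comparison: t when the differences pass
    Shapiro-Wilk, Wilcoxon signed-rank otherwise. Two-tailed either way."""
    d = np.asarray(sample_a, dtype=float) - np.asarray(sample_b, dtype=float)
    # the gate needs n >= 3; below that only the t-test is defined anyway
    branch = normality_gate(d) if len(d) >= 3 else PARAMETRIC
    if branch == PARAMETRIC:
        return paired_t(sample_a, sample_b)
    return wilcoxon_signed_rank(sample_a, sample_b)
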