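"""Study-level statistics: unpaired t tests (also from printed summaries),
Shapiro-Wilk normality, and Pearson chi-square for categorical outcomes.

Group results are reported as mean +- SD per arm with n animals; because
published tables carry only those summaries, :func:`ttest_from_summary`
recomputes the two-tailed unpaired t test directly from (mean, sd, n) pairs.
Both the pooled-variance (classic Student) and Welch variants are available;
pooled is the default.  :func:`ttest_from_samples` is defined as the summary
test applied to the samples' own statistics, so the two paths agree exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupStats:
    """Summary of one study arm: n, mean, standard deviation."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("standard deviation cannot be negative")

    @classmethod
    def from_sample(cls, label: str, sample) -> "GroupStats":
        x = np.asarray(sample, dtype=float)
        return cls(label=label, n=len(x), mean=float(np.mean(x)),
                   sd=float(np.std(x, ddof=1)))


@dataclass
class TestResult:
    """Outcome of a hypothesis test: statistic, degrees of freedom, two-tailed p."""

    statistic: float
    df: float
    p: float
    variant: str = ""
    kind: str = ""

    def __str__(self) -> str:
        name = self.kind or "test"
        return (f"{name}: statistic={self.statistic:.4g}, df={self.df:.4g}, "
                f"p={format_p(self.p)}" + (f" ({self.variant})" if self.variant else ""))


def format_p(p: float) -> str:
    """Render a p-value the way result tables print it (3 decimals, floored)."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def ttest_from_summary(a: GroupStats, b: GroupStats,
                       variant: str = "pooled") -> TestResult:
    """Two-tailed unpaired t test from per-group (mean, sd, n) summaries.

    pooled: t = (m_a - m_b) / sqrt(s_p^2 (1/n_a + 1/n_b)) with the pooled
    variance s_p^2 and df = n_a + n_b - 2.  welch: unpooled variances with
    Welch-Satterthwaite df.  Degenerate zero-variance groups: equal means
    give p = 1 by convention; different means give p = 0 with a warning.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    diff = a.mean - b.mean
    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            return TestResult(0.0, a.n + b.n - 2, 1.0, variant, "t")
        warnings.warn("zero variance in both groups with unequal means; p = 0")
        return TestResult(np.inf if diff > 0 else -np.inf, a.n + b.n - 2, 0.0,
                          variant, "t")
    va, vb = a.sd ** 2, b.sd ** 2
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        ra, rb = va / a.n, vb / b.n
        se = np.sqrt(ra + rb)
        df = (ra + rb) ** 2 / (ra ** 2 / (a.n - 1) + rb ** 2 / (b.n - 1))
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), variant, "t")


def ttest_from_samples(a, b, variant: str = "pooled") -> TestResult:
    """Two-tailed unpaired t test on raw samples.

    Defined as :func:`ttest_from_summary` on the samples' own mean/sd/n, so
    the two entry points cannot disagree.
    """
    return ttest_from_summary(GroupStats.from_sample("a", a),
                              GroupStats.from_sample("b", b), variant)


def shapiro_wilk(sample) -> TestResult:
    """Shapiro-Wilk normality test (W statistic, two-sided p)."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return TestResult(float(w), float(len(x)), float(p), "", "shapiro-wilk")


def chi_square_test(table) -> TestResult:
    """Pearson chi-square on a contingency table, without continuity correction.

    df = (rows - 1) x (cols - 1); for the study's 2x2 comparisons df = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty contingency table")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(expected == 0):
        raise ValueError("table has a zero row or column margin")
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(chi2, float(df), p, "", "chi-square")


def comparison_table(rows: list[tuple[str, GroupStats, GroupStats]],
                     variant: str = "pooled"):
    """Tabulate mean +- SD per arm and the t-test p for several endpoints."""
    import pandas as pd

    out = []
    for name, a, b in rows:
        res = ttest_from_summary(a, b, variant)
        out.append({
            "parameter": name,
            a.label: f"{a.mean:g} ± {a.sd:g}",
            b.label: f"{b.mean:g} ± {b.sd:g}",
            "t": round(res.statistic, 2),
            "df": round(res.df, 2),
            "p": format_p(res.p),
        })
    return pd.DataFrame(out)
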