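"""Statistical tests for derived swimming quantities.

Pooled-variance two-sample t-tests (the plain reading of "two-sample
t-test"; Welch available via a flag), one-way ANOVA from the standard
between/within decomposition, and Tukey HSD pairwise comparisons.
Significance is evaluated at alpha = 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = ["GroupSamples", "TestResult", "two_sample_t", "one_way_anova", "tukey_hsd"]


@dataclass
class GroupSamples:
    """Labelled groups of real-valued samples."""

    groups: dict  # label -> 1D array
    alpha: float = 0.05

    def __post_init__(self):
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for k, v in self.groups.items():
            if v.size < 2:
                raise ValueError(f"group {k} has fewer than 2 samples")

    def values(self):
        return list(self.groups.values())


@dataclass
class TestResult:
    statistic: float
    df: tuple
    p: float
    significant: bool
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)


def two_sample_t(x, y, alpha: float = 0.05, welch: bool = False) -> TestResult:
    """Two-sample t-test, two-sided. Pooled variance by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)) \
            if se2 > 0 else float(nx + ny - 2)
        se = np.sqrt(se2)
    else:
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(statistic=float(t), df=(df,), p=p,
                      significant=p < alpha, alpha=alpha)


def one_way_anova(samples: GroupSamples) -> TestResult:
    """One-way fixed-effects ANOVA (between/within decomposition).

    Degenerate case: identical constant groups return F = 0, p = 1 (no
    evidence of any difference); unequal constants with zero within-group
    variance return F = inf, p = 0.
    """
    groups = samples.values()
    k = len(groups)
    n = sum(g.size for g in groups)
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ssw == 0:
        if ssb == 0:
            return TestResult(statistic=0.0, df=(df_b, df_w), p=1.0,
                              significant=False, alpha=samples.alpha)
        return TestResult(statistic=float("inf"), df=(df_b, df_w), p=0.0,
                          significant=True, alpha=samples.alpha)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return TestResult(statistic=float(f), df=(df_b, df_w), p=p,
                      significant=p < samples.alpha, alpha=samples.alpha)


def tukey_hsd(samples: GroupSamples) -> dict:
    """Tukey's HSD pairwise comparisons (studentized range).

    Returns {(label_a, label_b): TestResult} with adjusted p-values.
    """
    labels = list(samples.groups)
    res = sps.tukey_hsd(*samples.values())
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            out[(labels[i], labels[j])] = TestResult(
                statistic=float(res.statistic[i, j]), df=(), p=p,
                significant=p < samples.alpha, alpha=samples.alpha)
    return out
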