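"""Gated statistical battery for per-subject TRF metrics.

Every comparison is first gated: parametric tests (two-sample / paired t)
are used only when every sample passes an Anderson--Darling normality test at
alpha = 0.05 and contains no point outside the 1.5 IQR fences; otherwise the
nonparametric counterpart (Mann--Whitney U / Wilcoxon signed-rank) is used.
Three or more samples route to Kruskal--Wallis. All tests are two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SubjectMetrics",
    "TestResult",
    "gate_test_choice",
    "compare",
    "bh_fdr",
    "running_paired_ttest_fdr",
    "partial_correlation",
    "latency_contrast",
    "cohens_d",
]


@dataclass
class SubjectMetrics:
    """Per-subject quantities entering the group statistics."""

    subject_id: str
    group: Literal["younger", "older"]
    age: float
    delta_r: dict[str, float] = field(default_factory=dict)
    peak_latency_ms: dict[str, float] = field(default_factory=dict)
    fluency_semantic: float | None = None
    fluency_letter: float | None = None


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    effect_size: float | None = None
    gating_path: Literal["parametric", "nonparametric"] = "parametric"

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _has_iqr_outlier(x: np.ndarray) -> bool:
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    return bool(np.any((x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)))


def gate_test_choice(
    *samples: Sequence[float], alpha: float = 0.05
) -> Literal["parametric", "nonparametric"]:
    """Route to parametric tests only for normal, outlier-free samples.

    Normality via Anderson--Darling at ``alpha``; outliers via the 1.5 IQR
    fences. Samples with n < 4 route nonparametric with a warning.
    """
    for x in samples:
        x = np.asarray(x, dtype=float)
        if x.size < 4:
            warnings.warn("sample too small for normality gating; nonparametric")
            return "nonparametric"
        if np.ptp(x) == 0:
            return "nonparametric"
        try:
            res = sps.anderson(x, dist="norm", method="interpolate")
            ad_p = float(res.pvalue)
        except TypeError:  # older scipy: critical-value interface
            res = sps.anderson(x, dist="norm")
            idx = int(np.argmin(np.abs(np.asarray(res.significance_level) / 100 - alpha)))
            ad_p = 1.0 if res.statistic <= res.critical_values[idx] else 0.0
        if ad_p <= alpha:
            return "nonparametric"
        if _has_iqr_outlier(x):
            return "nonparametric"
    return "parametric"


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Cohen's d; pooled-sd formulation for independent samples."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if paired:
        d = a - b
        return float(d.mean() / d.std(ddof=1))
    na, nb = a.size, b.size
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / sp)


_EXACT_N = 25


def compare(
    *samples: Sequence[float], paired: bool = False
) -> TestResult:
    """Gated two-or-more-sample comparison.

    Two samples: two-sample t / Mann--Whitney U (independent) or paired t /
    Wilcoxon signed-rank (paired), chosen by :func:`gate_test_choice`; Cohen's
    d accompanies t-tests. Three or more samples: Kruskal--Wallis.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValueError("need at least two samples")
    if len(arrays) > 2:
        stat, p = sps.kruskal(*arrays)
        return TestResult(
            "kruskal-wallis", float(stat), float(p),
            n=sum(a.size for a in arrays), gating_path="nonparametric",
        )
    a, b = arrays
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal length")
    path = gate_test_choice(a - b) if paired else gate_test_choice(a, b)
    if path == "parametric":
        if paired:
            stat, p = sps.ttest_rel(a, b)
            name = "paired-t"
        else:
            stat, p = sps.ttest_ind(a, b)
            name = "two-sample-t"
        return TestResult(
            name, float(stat), float(p), n=a.size + b.size,
            effect_size=cohens_d(a, b, paired=paired), gating_path=path,
        )
    if paired:
        diff = a - b
        if np.all(diff == 0):
            # degenerate signed-rank: no information, fail to reject
            return TestResult("wilcoxon", 0.0, 1.0, n=a.size, gating_path=path)
        method = "exact" if a.size <= _EXACT_N and not np.any(diff == 0) else "auto"
        stat, p = sps.wilcoxon(a, b, method=method)
        return TestResult("wilcoxon", float(stat), float(p), n=a.size, gating_path=path)
    method = "exact" if max(a.size, b.size) <= _EXACT_N else "auto"
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        "mann-whitney-u", float(stat), float(p), n=a.size + b.size,
        gating_path=path,
    )


def bh_fdr(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Benjamini--Hochberg step-up rejection mask."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresholds
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        mask[order[: k + 1]] = True
    return mask


def running_paired_ttest_fdr(
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired t-test at every lag, BH-FDR corrected across lags.

    ``weights_a``/``weights_b`` are subject x lag matrices with aligned
    subjects and lags. Returns (significance mask, raw p-values) per lag.
    """
    A = np.asarray(weights_a, float)
    B = np.asarray(weights_b, float)
    if A.shape != B.shape:
        raise ValueError("weight matrices must have identical shapes")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    res = sps.ttest_rel(A, B, axis=0)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance lags (e.g. A == B)
    return bh_fdr(p, alpha=alpha), p


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariate: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing a covariate from both.

    Residuals come from least-squares fits with intercept; the p-value uses a
    t distribution with n - 3 degrees of freedom. A constant covariate
    reduces to a plain Pearson correlation (with a warning).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(covariate, float)
    if not (x.size == y.size == c.size):
        raise ValueError("x, y and covariate must have equal length")
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if np.ptp(c) == 0:
        warnings.warn("constant covariate; plain Pearson correlation returned")
        r, p = sps.pearsonr(x, y)
        return float(r), float(p)
    C = np.column_stack([np.ones(n), c])
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    # a variable collinear with the covariate leaves no residual variance
    if np.linalg.norm(rx) <= 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300) or \
       np.linalg.norm(ry) <= 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-300):
        warnings.warn("residual variance ~ 0 after covariate removal; r set to 0")
        return 0.0, 1.0
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 3
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


def latency_contrast(
    metrics: Sequence[SubjectMetrics], feature: str = "surprisal"
) -> tuple[TestResult, float]:
    """Group latency delay (older minus younger means) with a gated test."""
    older = [m.peak_latency_ms[feature] for m in metrics if m.group == "older"]
    younger = [m.peak_latency_ms[feature] for m in metrics if m.group == "younger"]
    if not older or not younger:
        raise ValueError("both groups must be populated")
    delay = float(np.mean(older) - np.mean(younger))
    return compare(older, younger), delay
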