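"""Normality-gated paired comparisons and the pooled variance test.

Two per-subject metric vectors (matched order) are compared with a paired
t-test when a Shapiro–Wilk test accepts normality for *both samples*
(p > 0.05 each); otherwise with a Wilcoxon signed-rank test.  The gate is
applied to the samples themselves rather than to their paired differences —
the latter is the textbook choice, but the protocol implemented here gates
on the two samples, so that is what the code does.  Zero differences are
dropped before ranking (the classical Wilcoxon treatment); if every
difference is zero the comparison is degenerate and raises.

Robustness of calibration across subjects is assessed with a classical
Levene test (group-mean centring) of the pre-calibration metric vector
against the *pooled* post-calibration sample, i.e. the concatenation of the
per-subject values from both calibration methods — so with n subjects the
post group holds 2n values and the reported degrees of freedom are
(k - 1, N - k) = (1, 3n - 2).

All tests are two-sided at the 0.05 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA_GATE = 0.05


class DegenerateComparisonError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass(frozen=True)
class PairedComparison:
    """Outcome of a normality-gated paired comparison."""

    test_used: str  # "paired_t" or "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    gate_p_values: tuple[float, float]
    n: int
    df: int | None = None

    def to_dict(self) -> dict:
        return {
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "shapiro_p_a": self.gate_p_values[0],
            "shapiro_p_b": self.gate_p_values[1],
            "n": self.n,
            "df": self.df,
        }


@dataclass(frozen=True)
class VarianceComparison:
    """Levene homoscedasticity test of pre vs pooled post-calibration values."""

    F_statistic: float
    p_value: float
    df: tuple[int, int]
    n_pre: int
    n_post: int

    def to_dict(self) -> dict:
        return {
            "F_statistic": self.F_statistic,
            "p_value": self.p_value,
            "df1": self.df[0],
            "df2": self.df[1],
            "n_pre": self.n_pre,
            "n_post": self.n_post,
        }


def compare_paired(a: np.ndarray, b: np.ndarray) -> PairedComparison:
    """Compare two matched per-subject metric vectors.

    Shapiro–Wilk gate at 0.05 on both samples selects between a paired
    t-test (both normal-looking) and an exact Wilcoxon signed-rank test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be matched 1-D vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 matched subjects")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite metric values")
    diffs = a - b
    if np.all(diffs == 0):
        raise DegenerateComparisonError("all paired differences are zero")

    gate = (float(sps.shapiro(a).pvalue), float(sps.shapiro(b).pvalue))
    if gate[0] > ALPHA_GATE and gate[1] > ALPHA_GATE:
        res = sps.ttest_rel(a, b)
        return PairedComparison(
            "paired_t", float(res.statistic), float(res.pvalue), gate, len(a),
            df=len(a) - 1,
        )
    # zero differences dropped before ranking; exact distribution when the
    # remaining differences are tie-free, normal approximation otherwise
    res = sps.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return PairedComparison(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), gate, len(a)
    )


def compare_variance(
    pre: np.ndarray, post_linear: np.ndarray, post_svr: np.ndarray
) -> VarianceComparison:
    """Levene test (mean centring) of pre vs pooled post-calibration values."""
    pre = np.asarray(pre, dtype=float)
    post = np.concatenate(
        [np.asarray(post_linear, dtype=float), np.asarray(post_svr, dtype=float)]
    )
    if len(pre) < 3 or len(post) < 3:
        raise ValueError("need at least 3 values per group")
    if not (np.isfinite(pre).all() and np.isfinite(post).all()):
        raise ValueError("non-finite metric values")
    res = sps.levene(pre, post, center="mean")
    N, k = len(pre) + len(post), 2
    return VarianceComparison(
        float(res.statistic), float(res.pvalue), (k - 1, N - k), len(pre), len(post)
    )
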