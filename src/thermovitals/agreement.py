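"""Method-agreement statistics: Bland-Altman, agreement rate, Pearson, RMSE,
and the normality-gated group-comparison decision tree.

Bland-Altman summarizes paired method-vs-reference differences by their mean
(bias) and sample SD (n-1), with limits of agreement (LOA) at bias +/- 1.96 SD
— the fixed normal-approximation multiplier, not a t quantile.  The agreement
rate is the percentage of differences falling within the LOA, boundaries
counted as inside; for normally distributed differences it converges to ~95 %.

Group comparison follows a fixed decision tree: Shapiro-Wilk normality on each
group; if both pass (p >= alpha), Bartlett's equal-variance test; if variances
are equal, Student's t-test; any failure along the way falls through to the
Mann-Whitney U test.  The report records the path taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "ComparisonResult",
    "bland_altman",
    "rmse",
    "compare_groups",
    "bland_altman_plot",
    "scatter_plot",
]

LOA_MULTIPLIER = 1.96


@dataclass
class ComparisonResult:
    """Outcome of the group-comparison decision tree."""

    test_name: str  # "t-test" | "mann-whitney"
    statistic: float
    p_value: float
    normal_a_p: float
    normal_b_p: float
    equal_var_p: float | None  # None when normality already failed


@dataclass
class AgreementReport:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    agreement_rate_pct: float
    pearson_r: float | None
    pearson_p: float | None
    rmse: float
    comparison: ComparisonResult

    def to_dict(self) -> dict:
        return asdict(self)


def rmse(method: np.ndarray, reference: np.ndarray) -> float:
    """Root mean square of the paired differences."""
    method = np.asarray(method, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if method.shape != reference.shape:
        raise ValueError("paired series must have equal length")
    return float(np.sqrt(np.mean((method - reference) ** 2)))


def compare_groups(
    a: np.ndarray, b: np.ndarray, alpha: float = 0.05
) -> ComparisonResult:
    """Shapiro-Wilk -> Bartlett -> Student's t, falling back to Mann-Whitney U."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs at least 3 observations")
    # Shapiro-Wilk is undefined for a zero-range sample; route it nonparametric
    p_a = float(stats.shapiro(a).pvalue) if a.std() > 0 else 0.0
    p_b = float(stats.shapiro(b).pvalue) if b.std() > 0 else 0.0
    equal_var_p: float | None = None
    if p_a >= alpha and p_b >= alpha:
        equal_var_p = float(stats.bartlett(a, b).pvalue)
        if equal_var_p >= alpha:
            res = stats.ttest_ind(a, b, equal_var=True)
            return ComparisonResult(
                "t-test", float(res.statistic), float(res.pvalue), p_a, p_b, equal_var_p
            )
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(
        "mann-whitney", float(res.statistic), float(res.pvalue), p_a, p_b, equal_var_p
    )


def bland_altman(
    method: np.ndarray, reference: np.ndarray, alpha: float = 0.05
) -> AgreementReport:
    """Full agreement report for paired method/reference measurements."""
    method = np.asarray(method, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if method.shape != reference.shape:
        raise ValueError("method and reference must be paired (equal length)")
    n = method.size
    if n < 3:
        raise ValueError("need at least 3 pairs")

    diffs = method - reference
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa_low = bias - LOA_MULTIPLIER * sd
    loa_high = bias + LOA_MULTIPLIER * sd
    # boundary points count as inside; tolerance absorbs float round-off
    eps = 1e-12 * max(1.0, float(np.abs(diffs).max()))
    within = (diffs >= loa_low - eps) & (diffs <= loa_high + eps)
    agreement_pct = 100.0 * float(within.mean())

    if method.std() == 0 or reference.std() == 0:
        r = p = None  # Pearson undefined for a constant series
    else:
        rr = stats.pearsonr(method, reference)
        r, p = float(rr.statistic), float(rr.pvalue)

    return AgreementReport(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        agreement_rate_pct=agreement_pct,
        pearson_r=r,
        pearson_p=p,
        rmse=rmse(method, reference),
        comparison=compare_groups(method, reference, alpha=alpha),
    )


def bland_altman_plot(
    method: np.ndarray, reference: np.ndarray, path: str, title: str = ""
) -> AgreementReport:
    """Bland-Altman plot (differences vs means, bias and LOA lines) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = bland_altman(method, reference)
    method = np.asarray(method, float)
    reference = np.asarray(reference, float)
    means = (method + reference) / 2.0
    diffs = method - reference
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=18, alpha=0.7)
    ax.axhline(report.bias, ls=":", color="k", label=f"bias {report.bias:.3g}")
    for loa in (report.loa_low, report.loa_high):
        ax.axhline(loa, ls="--", color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("method - reference")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return report


def scatter_plot(
    method: np.ndarray, reference: np.ndarray, path: str, title: str = ""
) -> None:
    """Scatter of method vs reference with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    method = np.asarray(method, float)
    reference = np.asarray(reference, float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(reference, method, s=18, alpha=0.7)
    lims = [min(reference.min(), method.min()), max(reference.max(), method.max())]
    ax.plot(lims, lims, ls=":", color="k")
    ax.set_xlabel("reference")
    ax.set_ylabel("method")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
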