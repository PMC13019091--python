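"""Cohort-level statistics on WPA, class counts, and marker intensities.

Contrasts between groups use Welch's t-test when both groups pass a
Shapiro–Wilk normality check (α = 0.05) and the Mann–Whitney test otherwise
(exact null for combined n ≤ 20 without ties, normal approximation with tie
correction above).  Age associations use ordinary least-squares regression
with R² the squared Pearson correlation.  Results are reported as mean ± SD
for normal data and median with a distribution-free (order-statistic) 95 %
confidence interval otherwise.  No multiple-testing correction is applied —
each test is reported at its nominal level, so p-values across many outcomes
must be read accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StatResult", "contrast", "age_regression", "condition_response",
           "median_ci", "mannwhitney_exact"]

_SHAPIRO_ALPHA = 0.05
_EXACT_MAX_N = 20


@dataclass
class StatResult:
    test: str
    estimate: float            # difference of centers, slope, or fold change
    statistic: float
    p_value: float
    n_per_group: tuple
    reporting: str             # "mean±SD" | "median+95%CI"
    r_squared: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def median_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 3:
        return float("nan"), float("nan")
    alpha = 1.0 - level
    lo = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi = int(stats.binom.isf(alpha / 2, n, 0.5))
    lo = max(lo, 0)
    hi = min(hi, n - 1)
    return float(x[lo]), float(x[hi])


def _is_normal(values: np.ndarray) -> bool:
    if np.ptp(values) == 0:
        return False  # degenerate; Shapiro is undefined on constants
    return stats.shapiro(values).pvalue > _SHAPIRO_ALPHA


def mannwhitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by enumeration over rank assignments.

    Handles ties by enumerating group assignments of the pooled sample and
    comparing U statistics; intended for small samples (combined n ≤ ~12).
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(b) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def contrast(group_a, group_b, mode: str = "auto",
             labels: tuple[str, str] = ("a", "b")) -> StatResult:
    """Two-group contrast with normality-dependent test selection.

    ``mode='auto'`` picks Welch's t when both groups pass Shapiro–Wilk,
    otherwise Mann–Whitney.  The estimate is the difference of means (Welch)
    or medians (Mann–Whitney), b relative to a reversed: ``a − b``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if mode not in ("auto", "welch", "mannwhitney"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode == "auto":
        mode = "welch" if (_is_normal(a) and _is_normal(b)) else "mannwhitney"

    if mode == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        out = StatResult(
            test="welch_t",
            estimate=float(a.mean() - b.mean()),
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n_per_group=(len(a), len(b)),
            reporting="mean±SD",
            extra={"mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
                   "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
                   "groups": labels},
        )
        return out

    n_combined = len(a) + len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n_combined
    if n_combined <= _EXACT_MAX_N:
        if has_ties and n_combined <= 14:
            u, p = mannwhitney_exact(a, b)
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            u, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    ci_a, ci_b = median_ci(a), median_ci(b)
    return StatResult(
        test="mannwhitney",
        estimate=float(np.median(a) - np.median(b)),
        statistic=u,
        p_value=min(1.0, p),
        n_per_group=(len(a), len(b)),
        reporting="median+95%CI",
        ci_low=ci_a[0], ci_high=ci_a[1],
        extra={"median_a": float(np.median(a)), "ci_a": ci_a,
               "median_b": float(np.median(b)), "ci_b": ci_b,
               "groups": labels},
    )


def age_regression(ages, outcome, stratum: str = "all") -> StatResult:
    """OLS regression of an outcome on donor age within a stratum.

    Slope and intercept from the normal equations; R² is the squared Pearson
    correlation; the two-sided p comes from the t distribution with n − 2
    degrees of freedom.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if x.size != y.size:
        raise ValueError("ages and outcome must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ages")
    res = stats.linregress(x, y)
    return StatResult(
        test=f"ols_age[{stratum}]",
        estimate=float(res.slope),
        statistic=float(res.slope / res.stderr) if res.stderr > 0 else float("inf"),
        p_value=float(res.pvalue),
        n_per_group=(x.size,),
        reporting="mean±SD",
        r_squared=float(res.rvalue ** 2),
        extra={"intercept": float(res.intercept), "stderr": float(res.stderr)},
    )


def condition_response(summaries: pd.DataFrame,
                       baseline: str = "baseline",
                       stimulated: str = "ADP") -> dict:
    """ADP response of a cohort: per-class means, fold changes, paired contrasts.

    ``summaries`` is the per-measurement table; replicates are averaged per
    donor and condition first.  Fold change is the stimulated cohort mean
    over the baseline cohort mean per class and for WPA; a class with
    baseline mean 0 reports an undefined (NaN) fold, never infinity.  Paired
    contrasts on WPA and CD62P MFI use the paired t-test when the
    within-donor differences pass Shapiro–Wilk, the Wilcoxon signed-rank
    test otherwise.
    """
    value_cols = [c for c in ("m1", "m2", "m3", "m4", "N", "wpa", "cd42b_mfi", "cd62p_mfi")
                  if c in summaries.columns]
    per_donor = (summaries.groupby(["donor_id", "condition"], sort=True)[value_cols]
                 .mean().reset_index())
    wide = per_donor.pivot(index="donor_id", columns="condition", values=value_cols)

    means, folds = {}, {}
    for col in value_cols:
        mb = float(wide[(col, baseline)].mean())
        ms = float(wide[(col, stimulated)].mean())
        means[col] = {baseline: mb, stimulated: ms}
        folds[col] = ms / mb if mb > 0 else float("nan")

    def _paired(col: str) -> StatResult | None:
        if col not in value_cols:
            return None
        d = (wide[(col, stimulated)] - wide[(col, baseline)]).dropna().to_numpy()
        if d.size < 3:
            return None
        if _is_normal(d):
            res = stats.ttest_rel(wide[(col, stimulated)].dropna(), wide[(col, baseline)].dropna())
            return StatResult(test=f"paired_t[{col}]", estimate=float(d.mean()),
                              statistic=float(res.statistic), p_value=float(res.pvalue),
                              n_per_group=(d.size,), reporting="mean±SD")
        if np.all(d == 0):
            return StatResult(test=f"wilcoxon[{col}]", estimate=0.0, statistic=0.0,
                              p_value=1.0, n_per_group=(d.size,), reporting="median+95%CI")
        res = stats.wilcoxon(d)
        return StatResult(test=f"wilcoxon[{col}]", estimate=float(np.median(d)),
                          statistic=float(res.statistic), p_value=float(res.pvalue),
                          n_per_group=(d.size,), reporting="median+95%CI")

    return {
        "means": means,
        "fold_change": folds,
        "paired_wpa": _paired("wpa"),
        "paired_cd62p": _paired("cd62p_mfi"),
    }
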