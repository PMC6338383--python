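"""Associations between symptom scores and clinical/cognitive outcomes.

Continuous outcomes are related to symptom scores with Kendall's rank
correlation (tau-b, tie-corrected — symptom counts are heavily tied
integers), with confidence intervals from the non-parametric bootstrap
(cases resampled, bias-corrected and accelerated, BCa).  Binary outcomes are
compared with Welch's unequal-variances t-test and summarized with Cohen's d.
Differences between two correlation coefficients that share the same
participants are assessed with the paired bootstrap of the tau difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    """One outcome x score-kind association in a results battery."""

    outcome: str
    timepoint: str
    score_kind: str
    statistic: str          # {"tau", "cohen_d"}
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    B: int
    ci_method: str = "BCa"
    seed: int | None = None


def kendall_tau(x, y) -> float:
    """Kendall tau-b rank correlation (tie-corrected)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined: one variable is constant")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def kendall_tau_test(x, y) -> tuple[float, float]:
    """(tau-b, two-sided p-value)."""
    res = stats.kendalltau(np.asarray(x, float), np.asarray(y, float), variant="b")
    return float(res.statistic), float(res.pvalue)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / len(a), vb / len(b)
    df = (se2a + se2b) ** 2 / (se2a**2 / (len(a) - 1) + se2b**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohen_d(a, b) -> float:
    """Standardized mean difference (a - b) over the df-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 observations")
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(pooled))


def contingency_chi2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("expected a 2x2 table of nonnegative counts")
    a, b = t[0]
    c, d = t[1]
    margins = np.array([a + b, c + d, a + c, b + d])
    if np.any(margins == 0):
        raise ValueError("zero margin: chi-square undefined")
    n = t.sum()
    chi2 = n * (a * d - b * c) ** 2 / margins.prod()
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def detectable_r(n: int, alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest correlation detectable at the given n, alpha and power.

    Fisher-z approximation: r = tanh((z_{1-alpha/2} + z_power) / sqrt(n - 3)).
    """
    if n <= 4:
        raise ValueError("need n > 4")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(np.tanh(z / np.sqrt(n - 3)))


def bca_ci(
    data: Sequence | tuple,
    statistic: Callable[..., float],
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated (BCa) bootstrap confidence interval.

    ``data`` is one array or a tuple of aligned arrays; cases (rows) are
    resampled jointly, so paired statistics bootstrap correctly.  The bias
    correction z0 comes from the fraction of bootstrap replicates below the
    point estimate, the acceleration from jackknife skewness.  When z0 is
    infinite (the statistic is constant over resamples) the interval falls
    back to the percentile method with a warning; with z0 = a = 0 the BCa
    endpoints are exactly the percentile endpoints.
    """
    if B < 100:
        warnings.warn(f"B={B} is small for a bootstrap interval", UserWarning, stacklevel=2)
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("all data arrays must share the same length")
    if rng is None:
        rng = np.random.default_rng(seed)

    theta_hat = float(statistic(*arrays))

    boot = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot[b] = statistic(*(a[idx] for a in arrays))
    boot = boot[np.isfinite(boot)]
    if len(boot) == 0:
        return (theta_hat, theta_hat)
    if np.all(boot == boot[0]) and boot[0] == theta_hat:
        return (theta_hat, theta_hat)  # degenerate data: point interval

    prop = np.mean(boot < theta_hat)
    if prop in (0.0, 1.0):
        warnings.warn(
            "bias correction unbounded; falling back to percentile interval",
            UserWarning,
            stacklevel=2,
        )
        lo, hi = np.percentile(boot, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        return (float(lo), float(hi))
    z0 = stats.norm.ppf(prop)

    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = statistic(*(a[mask] for a in arrays))
        mask[i] = True
    jmean = jack.mean()
    num = np.sum((jmean - jack) ** 3)
    den = 6.0 * np.sum((jmean - jack) ** 2) ** 1.5
    a_hat = num / den if den > 0 else 0.0

    return bca_endpoints(boot, z0, a_hat, level)


def bca_endpoints(boot, z0: float, a_hat: float, level: float = 0.95) -> tuple[float, float]:
    """BCa-adjusted percentile endpoints of a bootstrap distribution.

    With z0 = a_hat = 0 this is exactly the percentile interval.
    """
    boot = np.asarray(boot, dtype=float)
    z_alpha = stats.norm.ppf([(1 - level) / 2, (1 + level) / 2])
    adj = stats.norm.cdf(z0 + (z0 + z_alpha) / (1 - a_hat * (z0 + z_alpha)))
    lo, hi = np.percentile(boot, 100 * adj)
    return (float(lo), float(hi))


def compare_correlations(
    scores_a,
    scores_b,
    outcome,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, tuple[float, float]]:
    """Paired-bootstrap difference of two Kendall correlations with one outcome.

    Both score vectors must describe the same participants; each bootstrap
    resample draws participants once and computes
    tau(scores_a, outcome) - tau(scores_b, outcome).  Returns the observed
    difference and its BCa interval; "no difference" reads as the interval
    spanning 0.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores_a, scores_b and outcome must be equally long")

    def delta_tau(ai, bi, yi):
        ta = stats.kendalltau(ai, yi, variant="b").statistic
        tb = stats.kendalltau(bi, yi, variant="b").statistic
        return ta - tb

    est = float(delta_tau(a, b, y))
    if np.array_equal(a, b):
        return 0.0, (0.0, 0.0)
    ci = bca_ci((a, b, y), delta_tau, B=B, level=level, seed=seed)
    return est, ci


def association_battery(
    scores: pd.DataFrame,
    cohort,
    B: int = 2000,
    seed: int | None = None,
    group: str = "ADHD",
    level: float = 0.95,
    d_sign: str = "absent_minus_present",
) -> list[AssociationResult]:
    """Outcome x score-kind association table for one analysis group.

    Continuous outcomes get Kendall tau with a BCa interval and the tau test
    p-value; binary outcomes get Cohen's d with a BCa interval and the Welch
    t-test p-value.  ``d_sign`` fixes the d direction for binary outcomes:
    ``absent_minus_present`` (default; a higher score in the outcome-present
    group yields negative d) or ``present_minus_absent``.  Outcomes with
    fewer than 3 complete pairs are skipped with a warning.
    """
    if d_sign not in ("absent_minus_present", "present_minus_absent"):
        raise ValueError(f"unknown d_sign {d_sign!r}")
    rows = cohort.data if hasattr(cohort, "data") else cohort
    if group != "combined":
        rows = rows[rows["group"] == group]
    merged = scores.merge(rows, on="id", suffixes=("", "_cohort"))
    outcome_cols = [
        c for c in rows.columns if c.endswith(("_baseline", "_followup"))
    ]
    score_kinds = ("unweighted", "strength_weighted", "clustering_weighted")
    rng = np.random.default_rng(seed)
    results: list[AssociationResult] = []
    for col in outcome_cols:
        name, _, timepoint = col.rpartition("_")
        for kind in score_kinds:
            sub = merged[[kind, col]].dropna()
            if len(sub) < 3:
                warnings.warn(
                    f"outcome {col!r}: fewer than 3 complete pairs; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                break
            s = sub[kind].to_numpy(dtype=float)
            y = sub[col].to_numpy(dtype=float)
            binary = set(np.unique(y)) <= {0.0, 1.0}
            if binary:
                present, absent = s[y == 1], s[y == 0]
                if len(present) < 2 or len(absent) < 2:
                    warnings.warn(
                        f"outcome {col!r}: a binary level has < 2 cases; skipped",
                        UserWarning,
                        stacklevel=2,
                    )
                    break
                g1, g2 = (absent, present) if d_sign == "absent_minus_present" else (present, absent)
                est = cohen_d(g1, g2)
                _, _, p = welch_t(g1, g2)

                def d_stat(si, yi):
                    a1, a2 = si[yi == 0], si[yi == 1]
                    if d_sign == "present_minus_absent":
                        a1, a2 = a2, a1
                    if len(a1) < 2 or len(a2) < 2:
                        return np.nan
                    try:
                        return cohen_d(a1, a2)
                    except ValueError:
                        return np.nan

                ci = bca_ci((s, y), d_stat, B=B, level=level, rng=rng)
                stat_name = "cohen_d"
            else:
                est, p = kendall_tau_test(s, y)

                def tau_stat(si, yi):
                    return stats.kendalltau(si, yi, variant="b").statistic

                ci = bca_ci((s, y), tau_stat, B=B, level=level, rng=rng)
                stat_name = "tau"
            results.append(
                AssociationResult(
                    outcome=name,
                    timepoint=timepoint,
                    score_kind=kind,
                    statistic=stat_name,
                    estimate=est,
                    ci_low=ci[0],
                    ci_high=ci[1],
                    p=p,
                    n=len(sub),
                    B=B,
                    seed=seed,
                )
            )
    return results


def battery_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tabular view of an association battery, one row per result."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "timepoint": r.timepoint,
                "score_kind": r.score_kind,
                "statistic": r.statistic,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": round(r.p, 3),
                "n": r.n,
            }
            for r in results
        ]
    )
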