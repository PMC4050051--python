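"""Agreement statistics for repeated thickness measurements.

Implements the battery used to judge measurement repeatability:
paired differences with 95% confidence intervals, Bland-Altman limits
of agreement for small groups (mean difference +- 2 SD of the
differences), two-way single-measure absolute-agreement intraclass
correlation with F-based confidence intervals, absolute and relative
coefficients of repeatability (1.96 SD of the paired differences, the
relative form normalized by the grand mean of the measurements), and
one-way repeated-measures ANOVA on the session factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RepeatedMeasures:
    """n subjects x k sessions of one quantity (complete matrix)."""

    values: np.ndarray
    layer: str = ""
    field: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2D (subjects x sessions) matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 sessions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing cells are not allowed")


def paired_diff(a: np.ndarray, b: np.ndarray
                ) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Mean paired difference with its 95% CI and 2-SD limits of agreement.

    The CI uses the t distribution with n-1 degrees of freedom; the
    limits of agreement use the small-group rule mean +- 2 SD of the
    differences (sample SD, n-1 denominator).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sessions must be equal-length vectors")
    n = a.size
    if n < 2:
        raise ValueError("need n >= 2")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t = stats.t.ppf(0.975, n - 1)
    ci = (mean - t * sd / np.sqrt(n), mean + t * sd / np.sqrt(n))
    loa = (mean - 2 * sd, mean + 2 * sd)
    return mean, ci, loa


def bland_altman(a: np.ndarray, b: np.ndarray) -> dict:
    """Bland-Altman pairs plus the difference-vs-mean association test.

    Returns the per-subject means and differences together with the
    Pearson correlation of difference against mean and its p-value
    (the proportional-bias check).  Zero variance in the means makes
    the association undefined (``r`` = NaN, ``flag`` set).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    means = (a + b) / 2.0
    diffs = a - b
    if np.ptp(means) == 0 or np.ptp(diffs) == 0:
        return {"mean": means, "diff": diffs, "r": np.nan, "p": np.nan,
                "flag": "zero-variance"}
    r, p = stats.pearsonr(diffs, means)
    return {"mean": means, "diff": diffs, "r": float(r), "p": float(p),
            "flag": ""}


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way (rows=subjects, columns=sessions) mean squares."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    # guard float cancellation: clamp and snap negligible terms to zero
    eps = 1e-12 * max(ss_total, 1e-300)
    ss_err = max(ss_total - ss_rows - ss_cols, 0.0)
    if ss_cols < eps:
        ss_cols = 0.0
    if ss_err < eps:
        ss_err = 0.0
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_absolute(m: RepeatedMeasures, alpha: float = 0.05
                 ) -> tuple[float, tuple[float, float]]:
    """Two-way single-measure absolute-agreement ICC (ICC(A,1)).

    Computed from the two-way ANOVA decomposition,
    ``(MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))``, with the
    F-based confidence interval of McGraw & Wong.  Zero total variance
    leaves the ICC undefined (NaN).
    """
    x = m.values
    n, k = x.shape
    if np.ptp(x) == 0:
        return (np.nan, (np.nan, np.nan))
    msr, msc, mse = _anova_mean_squares(x)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else np.nan
    # McGraw & Wong F-based interval for ICC(A,1)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = ((a * msc + b * mse) ** 2
             / ((a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))))
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_l * mse)
                 / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse)
                 / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        ci = (float(lower), float(upper))
    else:
        ci = (np.nan, np.nan)
    return float(icc), ci


def coefficient_of_repeatability(d: np.ndarray, grand_mean: float
                                 ) -> tuple[float, float]:
    """Absolute and relative coefficient of repeatability.

    ``cr_abs = 1.96 SD(d)`` for the paired differences ``d``;
    ``cr_pct = 100 cr_abs / grand_mean`` with the grand mean of all
    measurements entering the differences (undefined if it is <= 0).
    """
    d = np.asarray(d, dtype=np.float64)
    if d.size < 2:
        raise ValueError("need n >= 2 differences")
    cr_abs = 1.96 * float(np.std(d, ddof=1))
    cr_pct = 100.0 * cr_abs / grand_mean if grand_mean > 0 else np.nan
    return cr_abs, cr_pct


def rm_anova(m: RepeatedMeasures) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on the session factor.

    ``F = MS_session / MS_(session x subject)`` with degrees of freedom
    ``(k-1, (k-1)(n-1))``.
    """
    x = m.values
    n, k = x.shape
    _, msc, mse = _anova_mean_squares(x)
    if mse == 0:
        if msc == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = msc / mse
    p = float(stats.f.sf(f, k - 1, (k - 1) * (n - 1)))
    return float(f), p


def build_report(measurements: pd.DataFrame,
                 comparisons: tuple[tuple[int, int], ...] = ((1, 2), (1, 3))
                 ) -> pd.DataFrame:
    """Repeatability report shaped like the study's agreement tables.

    ``measurements`` is long-format with columns ``subject``,
    ``session`` (1-based), ``layer``, ``field``, ``value``.  For every
    layer/field the report holds one row per session comparison with
    the mean difference (CI, LoA), ICC (CI), CR (absolute and %), and
    the repeated-measures ANOVA p over all sessions.
    """
    required = {"subject", "session", "layer", "field", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    rows = []
    for (layer, fieldname), grp in measurements.groupby(["layer", "field"],
                                                        sort=True):
        wide = grp.pivot(index="subject", columns="session", values="value")
        if wide.isna().any().any():
            raise ValueError(
                f"inconsistent subject sets across sessions for "
                f"{layer}/{fieldname}")
        sessions = sorted(wide.columns)
        x = wide[sessions].to_numpy()
        _, anova_p = rm_anova(RepeatedMeasures(x, layer, fieldname))
        for s1, s2 in comparisons:
            if s1 not in sessions or s2 not in sessions:
                continue
            a = wide[s1].to_numpy()
            b = wide[s2].to_numpy()
            mean_d, ci, loa = paired_diff(a, b)
            icc, icc_ci = icc_absolute(
                RepeatedMeasures(np.column_stack([a, b]), layer, fieldname))
            cr_abs, cr_pct = coefficient_of_repeatability(
                a - b, float(np.mean(np.concatenate([a, b]))))
            rows.append({
                "layer": layer, "field": fieldname,
                "comparison": f"R{s1}-R{s2}",
                "mean_1": float(np.mean(a)), "sd_1": float(np.std(a, ddof=1)),
                "mean_2": float(np.mean(b)), "sd_2": float(np.std(b, ddof=1)),
                "delta": mean_d, "ci_low": ci[0], "ci_high": ci[1],
                "loa_low": loa[0], "loa_high": loa[1],
                "icc": icc, "icc_ci_low": icc_ci[0], "icc_ci_high": icc_ci[1],
                "cr_abs": cr_abs, "cr_pct": cr_pct, "anova_p": anova_p})
    return pd.DataFrame(rows)
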