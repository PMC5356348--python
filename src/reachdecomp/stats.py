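"""The statistical battery: normality screen, rank contrasts, correlations.

Group contrasts follow the nonparametric route throughout — Shapiro-Wilk
screening recorded, medians with 25-75% IQRs as summaries, Mann-Whitney U
for stroke-vs-control differences — with Pearson correlation / simple
least-squares regression for associations and a pooled-variance t-test for
the age comparison.  All tests are two-sided at alpha = 0.05; no
multiple-testing correction is applied across the eight parameter
contrasts (a Holm option exists but defaults off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import PARAM_NAMES

#: exact Mann-Whitney p when n_x * n_y <= this and the data are tie-free
EXACT_MW_LIMIT = 400


@dataclass(frozen=True)
class GroupContrast:
    parameter: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    u_statistic: float
    p_value: float
    shapiro_p_a: float | None
    shapiro_p_b: float | None

    def __post_init__(self) -> None:
        if not (self.iqr_a[0] <= self.median_a <= self.iqr_a[1]):
            raise ValueError("group-A IQR must bracket the median")
        if not (self.iqr_b[0] <= self.median_b <= self.iqr_b[1]):
            raise ValueError("group-B IQR must bracket the median")


@dataclass(frozen=True)
class AssociationResult:
    x_name: str
    y_name: str
    r: float
    r2: float
    p_value: float
    n: int
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation, via scipy)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk defined for 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _tie_free(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size == pooled.size


def mann_whitney(x, y) -> dict:
    """Mann-Whitney U with median/IQR summaries.

    The p-value is exact (full null enumeration) whenever
    ``n_x * n_y <= EXACT_MW_LIMIT`` and the pooled sample is tie-free;
    otherwise the normal approximation with tie and continuity corrections
    is used.  The dict records which route was taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = x.size * y.size <= EXACT_MW_LIMIT and _tie_free(x, y)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    q_x = np.percentile(x, [25, 50, 75])
    q_y = np.percentile(y, [25, 50, 75])
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "median_x": float(q_x[1]), "iqr_x": (float(q_x[0]), float(q_x[2])),
        "median_y": float(q_y[1]), "iqr_y": (float(q_y[0]), float(q_y[2])),
    }


def pearson_and_regression(x, y, x_name: str = "x",
                           y_name: str = "y") -> AssociationResult:
    """Pearson r (two-sided p) plus the least-squares line; R^2 = r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    lr = sps.linregress(x, y)
    return AssociationResult(x_name, y_name, r=float(lr.rvalue),
                             r2=float(lr.rvalue ** 2), p_value=float(lr.pvalue),
                             n=int(x.size), slope=float(lr.slope),
                             intercept=float(lr.intercept))


def two_sample_t(x, y, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sided t-test; pooled variance by default, Welch on request.

    Returns (t, df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise ValueError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def contrast_parameters(params: pd.DataFrame, group_col: str = "group",
                        groups: tuple[str, str] = ("stroke", "control"),
                        holm: bool = False) -> list[GroupContrast]:
    """Stroke-vs-control contrast for each of A, tau, C, D1..D5.

    Per parameter: Shapiro-Wilk screen on each group (recorded, never
    gating), median + IQR summaries, Mann-Whitney two-sided p.  With
    ``holm`` the p-values are Holm-adjusted across the eight contrasts.
    """
    a, b = groups
    ga = params[params[group_col] == a]
    gb = params[params[group_col] == b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs at least 2 subjects")
    out = []
    for name in PARAM_NAMES:
        xa = ga[name].to_numpy(float)
        xb = gb[name].to_numpy(float)
        try:
            sw_a = shapiro_wilk(xa)[1]
        except ValueError:
            sw_a = None
        try:
            sw_b = shapiro_wilk(xb)[1]
        except ValueError:
            sw_b = None
        mw = mann_whitney(xa, xb)
        out.append(GroupContrast(
            parameter=name,
            median_a=mw["median_x"], iqr_a=mw["iqr_x"],
            median_b=mw["median_y"], iqr_b=mw["iqr_y"],
            u_statistic=mw["U"], p_value=mw["p"],
            shapiro_p_a=sw_a, shapiro_p_b=sw_b))
    if holm:
        order = np.argsort([c.p_value for c in out])
        k = len(out)
        adj, prev = {}, 0.0
        for rank, idx in enumerate(order):
            p = min(1.0, (k - rank) * out[idx].p_value)
            prev = max(prev, p)
            adj[idx] = prev
        out = [GroupContrast(c.parameter, c.median_a, c.iqr_a, c.median_b,
                             c.iqr_b, c.u_statistic, adj[i],
                             c.shapiro_p_a, c.shapiro_p_b)
               for i, c in enumerate(out)]
    return out


def contrasts_frame(contrasts: list[GroupContrast]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": c.parameter,
        "median_stroke": c.median_a,
        "iqr25_stroke": c.iqr_a[0], "iqr75_stroke": c.iqr_a[1],
        "median_control": c.median_b,
        "iqr25_control": c.iqr_b[0], "iqr75_control": c.iqr_b[1],
        "U": c.u_statistic, "p": c.p_value,
        "shapiro_p_stroke": c.shapiro_p_a, "shapiro_p_control": c.shapiro_p_b,
    } for c in contrasts])


def predict_long_term(metrics: pd.DataFrame, test_phases: pd.DataFrame,
                      predictor: str = "normalized_learning",
                      exclude: tuple[str, ...] = ()) -> AssociationResult:
    """Regression of long-term performance change on a training-derived predictor.

    ``predictor`` is either ``normalized_learning`` or
    ``normalized_performance_change``; ``exclude`` drops listed subjects
    (the analysis reports with-and-without variants for an outlier).
    """
    if predictor not in ("normalized_learning", "normalized_performance_change"):
        raise ValueError(f"unknown predictor {predictor!r}")
    merged = metrics.merge(test_phases, on="subject", how="inner",
                           suffixes=("", "_phase"))
    if exclude:
        merged = merged[~merged["subject"].isin(exclude)]
    if len(merged) < 3:
        raise ValueError("fewer than 3 matched subjects")
    if "long_term_change" not in merged:
        merged = merged.assign(long_term_change=(
            (merged["mt_pre1_ms"] - merged["mt_1month_ms"]) / merged["mt_pre1_ms"]))
    return pearson_and_regression(
        merged[predictor], merged["long_term_change"],
        x_name=predictor, y_name="long_term_change")
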