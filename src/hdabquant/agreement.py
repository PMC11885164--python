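"""Method-comparison and inter-rater agreement statistics.

Implements the validation statistics used when benchmarking semi-automatic
positivity quantification against manual counting and across raters:

* paired t-test (from raw rate vectors or from a printed mean/SD/n
  summary), with 95% CI of the mean difference and eta-squared effect size
  ``t^2 / (t^2 + df)``;
* intraclass correlation from the two-way subjects x raters ANOVA with
  *absolute agreement*, single (one rater) and average (mean of k raters)
  units, with the McGraw & Wong F-based 95% confidence intervals.  The
  SPSS "two-way mixed, absolute agreement" output uses these same
  formulas, so either naming convention applies;
* the Spearman-Brown step-up relating single- to average-measure
  reliability (algebraically identical to ICC(A,k) from ICC(A,1));
* Cronbach's alpha and the inter-item (rater x rater) Pearson matrix.

All p-values are two-tailed; the conventional alpha = 0.05 is a report
annotation, never a filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError

log = logging.getLogger(__name__)


@dataclass
class PairedSummary:
    """Printed summary of paired differences (percentage points)."""

    mean_diff: float
    sd_diff: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InvalidParameterError("need n >= 2 pairs")
        if self.sd_diff < 0:
            raise InvalidParameterError("sd_diff must be >= 0")


@dataclass
class AgreementResult:
    t: float = math.nan
    df: int = 0
    p_two_tailed: float = math.nan
    ci95: tuple = (math.nan, math.nan)
    eta_squared: float = math.nan
    pearson_r: float = math.nan
    icc_single: float = math.nan
    icc_single_ci95: tuple = (math.nan, math.nan)
    icc_average: float = math.nan
    icc_average_ci95: tuple = (math.nan, math.nan)
    cronbach_alpha: float = math.nan
    inter_item: pd.DataFrame | None = None
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "t": self.t,
            "df": self.df,
            "p_two_tailed": self.p_two_tailed,
            "ci95": list(self.ci95),
            "eta_squared": self.eta_squared,
            "pearson_r": self.pearson_r,
            "icc_single": self.icc_single,
            "icc_single_ci95": list(self.icc_single_ci95),
            "icc_average": self.icc_average,
            "icc_average_ci95": list(self.icc_average_ci95),
            "cronbach_alpha": self.cronbach_alpha,
            "flags": list(self.flags),
        }
        if self.inter_item is not None:
            d["inter_item"] = self.inter_item.to_dict()
        return d


def paired_t_from_summary(s: PairedSummary) -> AgreementResult:
    """Paired t-test from a mean/SD/n difference summary.

    ``t = mean / (sd / sqrt(n))`` on ``n - 1`` degrees of freedom;
    eta-squared is ``t^2 / (t^2 + df)``.  A zero SD with a zero mean is
    the degenerate no-difference case (p := 1); a zero SD with a non-zero
    mean yields an infinite t (p := 0, flagged).
    """
    df = s.n - 1
    res = AgreementResult(df=df)
    se = s.sd_diff / math.sqrt(s.n)
    if s.sd_diff == 0:
        if s.mean_diff == 0:
            res.t, res.p_two_tailed = 0.0, 1.0
            res.ci95 = (0.0, 0.0)
            res.eta_squared = 0.0
            res.flags.append("degenerate: zero variance and zero mean difference")
        else:
            res.t = math.inf if s.mean_diff > 0 else -math.inf
            res.p_two_tailed = 0.0
            res.ci95 = (s.mean_diff, s.mean_diff)
            res.eta_squared = 1.0
            res.flags.append("infinite t: zero variance, non-zero mean difference")
        return res
    t = s.mean_diff / se
    res.t = t
    res.p_two_tailed = float(2 * stats.t.sf(abs(t), df))
    tc = float(stats.t.ppf(0.975, df))
    res.ci95 = (s.mean_diff - tc * se, s.mean_diff + tc * se)
    res.eta_squared = t * t / (t * t + df)
    return res


def paired_t_from_vectors(a, b) -> AgreementResult:
    """Paired t between two equal-length rate vectors, plus Pearson r."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidParameterError("a and b must be equal-length 1-d vectors")
    d = a - b
    res = paired_t_from_summary(
        PairedSummary(float(d.mean()), float(d.std(ddof=1)), len(d))
    )
    if np.std(a) == 0 or np.std(b) == 0:
        res.flags.append("pearson r undefined: constant input vector")
    else:
        res.pearson_r = float(stats.pearsonr(a, b).statistic)
    return res


def _anova_two_way(m: np.ndarray):
    """Mean squares of the two-way subjects x raters decomposition."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def _as_matrix(m) -> np.ndarray:
    arr = np.asarray(m, dtype=float) if not isinstance(m, pd.DataFrame) else m.to_numpy(float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InvalidParameterError("need an n>=2 subjects x k>=2 raters matrix")
    if np.isnan(arr).any():
        raise InvalidParameterError(
            "rater matrix must be complete; drop incomplete subjects first"
        )
    return arr


def drop_incomplete_subjects(m: pd.DataFrame) -> pd.DataFrame:
    """Complete-case filter for ICC/alpha, logging how many rows dropped."""
    out = m.dropna()
    n_drop = len(m) - len(out)
    if n_drop:
        log.warning("dropped %d subject(s) with missing ratings", n_drop)
    return out


def icc_two_way(m, unit: str = "single", alpha: float = 0.05):
    """Absolute-agreement intraclass correlation with 95% CI.

    From the two-way ANOVA mean squares (MSR between subjects, MSC between
    raters, MSE residual)::

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

    Confidence bounds follow McGraw & Wong's F approximation; average-
    measure bounds are the Spearman-Brown step-up of the single-measure
    bounds.  Returns ``(icc, (low, high), flags)``.
    """
    if unit not in ("single", "average"):
        raise InvalidParameterError("unit must be 'single' or 'average'")
    arr = _as_matrix(m)
    n, k = arr.shape
    msr, msc, mse = _anova_two_way(arr)
    flags = []
    denom_s = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom_s <= 0:
        raise InvalidParameterError("degenerate rater matrix (non-positive variance)")
    icc1 = (msr - mse) / denom_s
    if msr <= mse:
        flags.append("unreliable: between-subject variance not above error")
    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse > 0:
        fj = msc / mse
        a = (k * icc1) / (n * (1 - icc1)) if icc1 < 1 else math.inf
        if math.isinf(a):
            lo1 = hi1 = 1.0
        else:
            vn = (k - 1) * (n - 1) * (
                (k * icc1 * fj + n * (1 + (k - 1) * icc1) - k * icc1) ** 2
            )
            vd = (n - 1) * k**2 * icc1**2 * fj**2 + (
                n * (1 + (k - 1) * icc1) - k * icc1
            ) ** 2
            v = vn / vd
            f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (msr - f_u * mse) / (
                f_u * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi1 = n * (f_l * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_l * msr
            )
    else:
        lo1 = hi1 = icc1
        flags.append("zero residual variance: CI collapsed")
    if unit == "single":
        return float(icc1), (float(lo1), float(hi1)), flags
    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    return float(icc_k), (_step_up(lo1, k), _step_up(hi1, k)), flags


def _step_up(r: float, k: int) -> float:
    """Spearman-Brown step-up without range checks (for CI bounds).

    A single-measure bound at or below -1/(k-1) puts the stepped-up bound
    past the negative singularity; report -inf there.
    """
    denom = 1 + (k - 1) * r
    if denom <= 0:
        return float("-inf")
    return float(k * r / denom)


def spearman_brown(icc_single: float, k: int) -> float:
    """Reliability of the mean of k raters from single-rater reliability."""
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    if icc_single <= -1.0 / (k - 1):
        raise InvalidParameterError("icc_single out of the valid step-up range")
    return k * icc_single / (1 + (k - 1) * icc_single)


def cronbach_alpha(m) -> float:
    """Internal consistency: (k/(k-1)) (1 - sum item variances / total)."""
    arr = _as_matrix(m)
    k = arr.shape[1]
    item_var = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise InvalidParameterError("zero total variance; alpha undefined")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))


def inter_item_matrix(m) -> pd.DataFrame:
    """Pairwise Pearson correlations between rater columns."""
    if not isinstance(m, pd.DataFrame):
        m = pd.DataFrame(np.asarray(m, dtype=float))
    _as_matrix(m)
    const = [c for c in m.columns if m[c].nunique() <= 1]
    if const:
        log.warning("constant rater column(s): %s", const)
    corr = m.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in const:
        corr.loc[c, corr.columns != c] = np.nan
        corr.loc[corr.index != c, c] = np.nan
    return corr


def rater_agreement(m) -> AgreementResult:
    """Full inter-rater report: ICC single/average + CIs, alpha, inter-item."""
    if isinstance(m, pd.DataFrame):
        m = drop_incomplete_subjects(m)
    res = AgreementResult()
    res.icc_single, res.icc_single_ci95, flags = icc_two_way(m, "single")
    res.icc_average, res.icc_average_ci95, _ = icc_two_way(m, "average")
    res.cronbach_alpha = cronbach_alpha(m)
    res.inter_item = inter_item_matrix(m)
    res.flags.extend(flags)
    return res
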