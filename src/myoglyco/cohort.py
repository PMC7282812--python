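"""Cohort statistics: group tests, correlation inference, variance components.

Group comparisons between the MHN and MHS diagnostic classes use a
two-sample t-test when both groups show evidence of normality
(Shapiro-Wilk) and equal variance (median-centered Levene); otherwise the
Mann-Whitney u test.  Correlation significance uses the exact-null
statistic

    t = r sqrt(n-2) / sqrt(1 - r^2)   ~  Student t with n-2 df

and, as a large-sample alternative appropriate for large |r|, the Fisher
z-statistic

    v = sqrt(n-3) * (1/2) ln((1+r)/(1-r))   ~  N(0, 1).

A nested replicate design (lanes within patients, repeated evaluations
within lanes) yields fractional variance components from which the
irreducible single-measurement SD and probable-error thresholds follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "VarianceDecomposition",
    "compare_groups",
    "correlation_pvalues",
    "pearson_with_p",
    "percent_difference",
    "multivariate_regression",
    "variance_decomposition",
    "variance_decomposition_from_components",
    "select_mc_mn",
    "fbs_excess_estimate",
]


@dataclass
class GroupComparison:
    variable: str
    n_mhn: int
    n_mhs: int
    mean_mhn: float
    mean_mhs: float
    median_mhn: float
    median_mhs: float
    sem_mhn: float
    sem_mhs: float
    test_used: str  # "t" | "mann_whitney"
    p: float
    direction: str  # "increase" | "decrease" | "none"


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    n: int
    r: float
    t_stat: float
    v_stat: float
    p_t: float
    p_v: float
    df_convention: str = "n_minus_2"


@dataclass
class VarianceDecomposition:
    """Fractional variance components of a nested replicate design.

    All variances are fractions of the squared patient mean.  The
    irreducible component (total minus technical) quantifies the true
    lane-to-lane scatter that repeated evaluation cannot remove;
    its square root is the SD of a single determination.
    """

    total_frac_var: float
    technical_frac_var: float

    def __post_init__(self) -> None:
        if self.total_frac_var < 0 or self.technical_frac_var < 0:
            raise ValueError("variances must be >= 0")
        if self.technical_frac_var > self.total_frac_var:
            warnings.warn(
                "technical variance exceeds total; irreducible floored at 0",
                stacklevel=2,
            )

    @property
    def irreducible_frac_var(self) -> float:
        return max(self.total_frac_var - self.technical_frac_var, 0.0)

    @property
    def sd_single(self) -> float:
        return float(np.sqrt(self.irreducible_frac_var))

    @property
    def threshold_2sd_percent(self) -> float:
        """Smallest between-individual difference assignable significance, %."""
        return 200.0 * self.sd_single

    def probable_error_of_mean_percent(self, n: int) -> float:
        """Probable error of an n-patient group mean, % of the measured value."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return self.threshold_2sd_percent / np.sqrt(n)


# ---------------------------------------------------------------------------


def _group_values(table: pd.DataFrame, variable: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table[["dx", variable]].dropna()
    g1 = sub.loc[sub["dx"] == "MHN", variable].to_numpy(dtype=float)
    g2 = sub.loc[sub["dx"] == "MHS", variable].to_numpy(dtype=float)
    return g1, g2


def compare_groups(table: pd.DataFrame, variable: str, alpha_gate: float = 0.05) -> GroupComparison:
    """MHN-vs-MHS comparison with the study's test-selection rule.

    t-test when Shapiro-Wilk accepts normality in both groups AND a
    median-centered Levene test accepts equal variances (both at the 0.05
    level); Mann-Whitney u test otherwise.  Two-tailed p throughout.
    """
    mhn, mhs = _group_values(table, variable)
    if len(mhn) < 3 or len(mhs) < 3:
        raise ValueError("need >= 3 non-missing values per group")
    if np.ptp(mhn) == 0 and np.ptp(mhs) == 0 and mhn[0] == mhs[0]:
        raise ValueError(f"{variable} is constant in both groups")

    normal = all(
        np.ptp(g) > 0 and stats.shapiro(g).pvalue > alpha_gate for g in (mhn, mhs)
    )
    equal_var = (
        np.ptp(mhn) > 0
        and np.ptp(mhs) > 0
        and stats.levene(mhn, mhs, center="median").pvalue > alpha_gate
    )
    if normal and equal_var:
        test_used = "t"
        p = float(stats.ttest_ind(mhn, mhs, equal_var=True).pvalue)
    else:
        test_used = "mann_whitney"
        p = float(stats.mannwhitneyu(mhn, mhs, alternative="two-sided").pvalue)

    mean_n, mean_s = float(mhn.mean()), float(mhs.mean())
    direction = "increase" if mean_s > mean_n else "decrease" if mean_s < mean_n else "none"
    return GroupComparison(
        variable=variable,
        n_mhn=len(mhn), n_mhs=len(mhs),
        mean_mhn=mean_n, mean_mhs=mean_s,
        median_mhn=float(np.median(mhn)), median_mhs=float(np.median(mhs)),
        sem_mhn=float(mhn.std(ddof=1) / np.sqrt(len(mhn))),
        sem_mhs=float(mhs.std(ddof=1) / np.sqrt(len(mhs))),
        test_used=test_used, p=min(p, 1.0), direction=direction,
    )


def correlation_pvalues(
    r: float, n: int, df_convention: str = "n_minus_2"
) -> tuple[float, float, float, float]:
    """Significance of a Pearson r at sample size n: (t, p_t, v, p_v).

    t = r·sqrt(n−2)/sqrt(1−r²) against Student t with n−2 df (the
    convention consistent with the stated degrees of freedom; pass
    ``df_convention='n'`` for the literal r·sqrt(n) numerator), and the
    Fisher z-statistic v = sqrt(n−3)·artanh(r) against N(0, 1).
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must be in [-1, 1]")
    if n < 4:
        raise ValueError("need n >= 4")
    df = n - 2
    numer = np.sqrt(n) if df_convention == "n" else np.sqrt(df)
    denom = np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    t_stat = float(r * numer / denom)
    p_t = float(2.0 * stats.t.sf(abs(t_stat), df))
    v_stat = float(np.sqrt(n - 3) * np.arctanh(r)) if abs(r) < 1 else float("inf")
    p_v = float(2.0 * stats.norm.sf(abs(v_stat)))
    return t_stat, p_t, v_stat, p_v


def pearson_with_p(
    x: np.ndarray,
    y: np.ndarray,
    pair: tuple[str, str] = ("x", "y"),
    df_convention: str = "n_minus_2",
) -> CorrelationResult:
    """Pearson r with significance by the exact-t and Fisher-z statistics.

    ``df_convention='n'`` reproduces the literal t = r·sqrt(n)/sqrt(1−r²)
    reading; the default uses sqrt(n−2), the form consistent with the stated
    n−2 degrees of freedom.  Pairs with missing values are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    t_stat, p_t, v_stat, p_v = correlation_pvalues(r, n, df_convention)
    return CorrelationResult(pair, n, r, t_stat, v_stat, p_t, p_v, df_convention)


def percent_difference(
    mhn_stat: float | pd.DataFrame,
    mhs_stat: float | None = None,
    variable: str | None = None,
    statistic: str = "mean",
) -> float:
    """Signed percent change of the MHS statistic relative to the MHN one.

    Either call with two scalar group statistics, or with a cohort table,
    variable name and statistic ("mean" or "median").  Returned at full
    precision; round to the nearest integer for reporting.
    """
    if isinstance(mhn_stat, pd.DataFrame):
        if variable is None:
            raise ValueError("variable required with a cohort table")
        mhn, mhs = _group_values(mhn_stat, variable)
        fn = np.mean if statistic == "mean" else np.median
        ref, val = float(fn(mhn)), float(fn(mhs))
    else:
        ref, val = float(mhn_stat), float(mhs_stat)
    if ref <= 0:
        raise ValueError("reference statistic must be positive")
    return 100.0 * (val - ref) / ref


@dataclass
class RegressionSummary:
    response: str
    predictors: list[str]
    n: int
    multivariate_r: float
    f_value: float
    p_f: float
    coefficients: pd.DataFrame  # index: predictor; columns: coef, se, t, p
    dropped: list[str]


def multivariate_regression(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    mode: str = "inverse",
) -> RegressionSummary | list[RegressionSummary]:
    """Ordinary least squares linking one variable to several others.

    ``inverse``: the response is modeled on all predictors jointly (one
    fit).  ``direct``: each variable in ``predictors`` is treated as a
    dependent variable regressed on the single ``response`` variable (a
    list of simple fits).  Listwise deletion of incomplete rows; exactly
    collinear predictors are dropped with a warning.
    """
    if mode == "direct":
        return [
            multivariate_regression(table, y, [response], mode="inverse")
            for y in predictors
        ]
    if mode != "inverse":
        raise ValueError(f"unknown mode {mode!r}")

    cols = [response] + list(predictors)
    data = table[cols].dropna()
    keep, dropped = [], []
    for pcol in predictors:
        trial = data[keep + [pcol]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(data)), trial])) == len(keep) + 2:
            keep.append(pcol)
        else:
            dropped.append(pcol)
    if dropped:
        warnings.warn(f"dropped collinear predictors: {dropped}", stacklevel=2)
    if not keep:
        raise ValueError("no usable predictors after collinearity drop")
    n = len(data)
    if n <= len(keep) + 2:
        raise ValueError("too few complete rows for the number of predictors")
    X = sm.add_constant(data[keep].to_numpy(dtype=float))
    fit = sm.OLS(data[response].to_numpy(dtype=float), X).fit()
    coef = pd.DataFrame(
        {
            "coef": fit.params[1:],
            "se": fit.bse[1:],
            "t": fit.tvalues[1:],
            "p": fit.pvalues[1:],
        },
        index=keep,
    )
    return RegressionSummary(
        response=response,
        predictors=keep,
        n=n,
        multivariate_r=float(np.sqrt(max(fit.rsquared, 0.0))),
        f_value=float(fit.fvalue),
        p_f=float(fit.f_pvalue),
        coefficients=coef,
        dropped=dropped,
    )


def variance_decomposition(replicates: pd.DataFrame) -> VarianceDecomposition:
    """Fractional variance components from a (patient, lane, tech_rep, value) table.

    A simple nested analysis of variance, per patient and expressed as a
    fraction of the squared patient mean: the technical component is the
    pooled mean square deviation of repeated evaluations about their lane
    mean; the lane (irreducible) component comes from the mean square of
    lane means about the patient mean after removing the technical
    contribution (MS_lanes − technical/n_reps); the total is their sum, an
    unbiased estimate of the variance of a single determination.
    """
    required = {"patient", "lane", "value"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicate table needs columns {sorted(required)}")
    lane_fracs, tech_fracs = [], []
    any_multirep = False
    for _, per_patient in replicates.groupby("patient"):
        m = per_patient["value"].to_numpy(dtype=float).mean()
        if m == 0:
            raise ValueError("zero patient mean; fractional variance undefined")
        lane_means, rep_counts, tech_here = [], [], []
        for _, per_lane in per_patient.groupby("lane"):
            lv = per_lane["value"].to_numpy(dtype=float)
            lane_means.append(lv.mean())
            rep_counts.append(lv.size)
            if lv.size > 1:
                any_multirep = True
                tech_here.append(lv.var(ddof=1) / m**2)
        tech_p = float(np.mean(tech_here)) if tech_here else 0.0
        tech_fracs.append(tech_p)
        if len(lane_means) > 1:
            ms_lanes = np.var(lane_means, ddof=1) / m**2
            lane_fracs.append(max(ms_lanes - tech_p / np.mean(rep_counts), 0.0))
    if not any_multirep:
        raise ValueError("technical variance undefined: no lane has repeated evaluations")
    tech = float(np.mean(tech_fracs))
    lane = float(np.mean(lane_fracs)) if lane_fracs else 0.0
    return VarianceDecomposition(lane + tech, tech)


def variance_decomposition_from_components(
    total_frac_var: float, technical_frac_var: float
) -> VarianceDecomposition:
    """Build the decomposition directly from already-computed components."""
    return VarianceDecomposition(total_frac_var, technical_frac_var)


def select_mc_mn(table: pd.DataFrame, k: int = 6) -> tuple[list[str], list[str]]:
    """Metabolically-challenged / metabolically-normal subgroup selection.

    Patients are ranked by the sum of their within-cohort ranks of
    microsomal PhK and GP content.  MC = the top-k among MHS patients;
    MN = the bottom-k of the whole cohort (flagged if any member is not
    MHN).  Ties break deterministically by patient id.
    """
    for col in ("PhK_mc", "GP_mc"):
        if table[col].isna().any():
            raise ValueError(f"{col} missing for some patients")
    df = table.sort_values("id").reset_index(drop=True)
    score = df["PhK_mc"].rank(method="average") + df["GP_mc"].rank(method="average")
    df = df.assign(_score=score)
    mhs = df[df["dx"] == "MHS"]
    if k > len(mhs) or k > len(df):
        raise ValueError("k exceeds group size")
    mc = (
        mhs.sort_values(["_score", "id"], ascending=[False, True])
        .head(k)["id"].tolist()
    )
    bottom = df.sort_values(["_score", "id"], ascending=[True, True]).head(k)
    mn = bottom["id"].tolist()
    non_mhn = bottom.loc[bottom["dx"] != "MHN", "id"].tolist()
    if non_mhn:
        warnings.warn(f"MN subgroup contains non-MHN patients: {non_mhn}", stacklevel=2)
    return mc, mn


def fbs_excess_estimate(slope_mM_per_unit: float, delta_ratio: float) -> float:
    """Excess fasting blood sugar implied by a shift of the phosphorylation ratio.

    Product of the FBS-vs-ratio regression slope (mM per unit ratio) and the
    between-group difference of the ratio, rounded to 2 decimals.
    """
    if not (np.isfinite(slope_mM_per_unit) and np.isfinite(delta_ratio)):
        raise ValueError("slope and delta must be finite")
    return round(float(slope_mM_per_unit) * float(delta_ratio), 2)
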