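"""Method-agreement and treatment-effect statistics.

Implements the analysis battery for comparing manual and automated
phenotyping: assumption-routed correlation (Pearson when the parametric
assumptions hold, Spearman otherwise), replicate-CV comparison via the
Wilcoxon signed-rank test, the ln(x+1) transform for zero-inflated trait
times, one-way ANOVA for distance moved across acclimation treatments,
two-way ANOVA (treatment × method, with interaction) for trait times, and
standard errors.

The parametric-assumption screen replaces visual QQ/scatterplot inspection
with deterministic quantitative surrogates (QQ correlation, the
interquartile-range outlier criterion, a Breusch–Pagan test and a quadratic
lack-of-fit test) so that routing is a pure, testable function of the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

QQ_NORMALITY_THRESHOLD = 0.975
ASSUMPTION_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Outliers and normality


def iqr_outliers(values, ids=None) -> list:
    """Ids of values outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation between order statistics (the
    convention matters: Tukey hinges can flag different points).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for the IQR criterion")
    if ids is None:
        ids = np.arange(len(values))
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (values < lo) | (values > hi)
    return [ids[i] for i in np.flatnonzero(mask)]


def qq_normality(values, threshold: float = QQ_NORMALITY_THRESHOLD) -> tuple[bool, float]:
    """Normality screen: correlation of the QQ plot against normal quantiles.

    Returns (ok, qq_r). Constant data are degenerate and fail.
    """
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0:
        return False, 0.0
    (_osm, _osr), (_s, _i, r) = sps.probplot(values, dist="norm")
    return bool(r >= threshold), float(r)


# ---------------------------------------------------------------------------
# Assumption-routed correlation


@dataclass(frozen=True)
class AssumptionReport:
    """Deterministic surrogate for the visual parametric-assumption checks."""

    normality_ok: dict
    outlier_ids: tuple
    homoscedasticity_ok: bool
    linearity_ok: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def parametric_ok(self) -> bool:
        return (
            all(self.normality_ok.values())
            and not self.outlier_ids
            and self.homoscedasticity_ok
            and self.linearity_ok
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Routed correlation; both coefficients are always reported."""

    method: str  # 'pearson' or 'spearman'
    coefficient: float
    p_value: float
    n: int
    r_squared: float | None
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float


def _assumption_report(x: np.ndarray, y: np.ndarray) -> AssumptionReport:
    norm_x, qq_x = qq_normality(x)
    norm_y, qq_y = qq_normality(y)
    outliers = tuple(iqr_outliers(x)) + tuple(
        len(x) + np.asarray(iqr_outliers(y), dtype=int)
    )
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    diagnostics = {"qq_r_x": qq_x, "qq_r_y": qq_y}
    if np.allclose(resid, 0.0, atol=1e-10 * max(1.0, float(np.std(y)))):
        homo_ok, lin_ok = True, True
        diagnostics["perfect_fit"] = True
    else:
        _lm, lm_p, _f, _fp = het_breuschpagan(resid, X)
        homo_ok = bool(lm_p > ASSUMPTION_ALPHA)
        diagnostics["breusch_pagan_p"] = float(lm_p)
        xs = (x - x.mean()) / x.std()
        Xq = sm.add_constant(np.column_stack([xs, xs**2]))
        quad = sm.OLS(y, Xq).fit()
        quad_p = float(quad.pvalues[2])
        lin_ok = bool(quad_p > ASSUMPTION_ALPHA)
        diagnostics["quadratic_term_p"] = quad_p
    return AssumptionReport(
        normality_ok={"x": norm_x, "y": norm_y},
        outlier_ids=outliers,
        homoscedasticity_ok=homo_ok,
        linearity_ok=lin_ok,
        diagnostics=diagnostics,
    )


def route_correlation(x, y) -> tuple[CorrelationResult, AssumptionReport]:
    """Pearson when all parametric assumptions pass, Spearman otherwise.

    Both coefficients are computed either way; the report records why the
    route was taken.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    report = _assumption_report(x, y)
    pr, pp = sps.pearsonr(x, y)
    sr, sp_ = sps.spearmanr(x, y)
    if report.parametric_ok:
        result = CorrelationResult(
            method="pearson",
            coefficient=float(pr),
            p_value=float(pp),
            n=len(x),
            r_squared=float(pr) ** 2,
            pearson_r=float(pr),
            pearson_p=float(pp),
            spearman_r=float(sr),
            spearman_p=float(sp_),
        )
    else:
        result = CorrelationResult(
            method="spearman",
            coefficient=float(sr),
            p_value=float(sp_),
            n=len(x),
            r_squared=None,
            pearson_r=float(pr),
            pearson_p=float(pp),
            spearman_r=float(sr),
            spearman_p=float(sp_),
        )
    return result, report


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int
    n_zeros: int
    method: str  # 'exact' or 'normal'


EXACT_N_MAX = 25


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p under random signs, by distributing the rank sum.

    Ranks are tie-averaged so doubled ranks are integers; the null
    distribution of 2·W⁺ is built by dynamic programming (equivalent to full
    enumeration of all 2ⁿ sign assignments).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on a − b.

    Zero differences are dropped (their count is reported), tied absolute
    differences get averaged ranks. The null is exact (full sign-assignment
    distribution) up to n = 25 and a tie-corrected normal approximation with
    continuity correction beyond.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    d = a - b
    nonzero = d != 0
    n_zeros = int((~nonzero).sum())
    d = d[nonzero]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _uniq, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        diff = w_plus - mean
        cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
        z = (diff - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "normal"
    return WilcoxonResult(w_plus, p, n, n_zeros, method)


# ---------------------------------------------------------------------------
# Transforms, ANOVA, standard errors


def log1p_transform(values):
    """ln(x + 1): compresses right-skewed trait times, keeps zeros at zero."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("ln(x+1) requires non-negative values")
    return np.log1p(values)


@dataclass
class AnovaTable:
    """Term-wise F table plus the residual df and the transform applied."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, F, PR(>F)
    df_resid: int
    transform_applied: str = "none"
    ss_type: int | str = 2

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def __str__(self) -> str:
        return (
            f"ANOVA (type {self.ss_type}, transform {self.transform_applied}, "
            f"residual df {self.df_resid})\n{self.table}"
        )


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
    typ: int | str = 2,
    transform_applied: str = "none",
) -> AnovaTable:
    """Two-way ANOVA (default: treatment × method with interaction).

    Unbalanced designs (exclusions leave unequal cells) use Type II sums of
    squares by default; the type is configurable and recorded. Empty cells
    are an error naming the cell.
    """
    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    cells = pd.crosstab(data[factor_a], data[factor_b])
    empty = cells.stack()[cells.stack() == 0]
    if len(empty):
        a, b = empty.index[0]
        raise ValueError(f"empty design cell: {factor_a}={a!r}, {factor_b}={b!r}")
    op = "*" if interaction else "+"
    formula = f"Q('{response}') ~ C(Q('{factor_a}')) {op} C(Q('{factor_b}'))"
    model = ols(formula, data=data).fit()
    table = anova_lm(model, typ=typ)
    table = table.rename(
        index=lambda s: (
            s.replace(f"C(Q('{factor_a}'))", factor_a).replace(
                f"C(Q('{factor_b}'))", factor_b
            )
        )
    )
    return AnovaTable(
        table=table,
        df_resid=int(model.df_resid),
        transform_applied=transform_applied,
        ss_type=typ,
    )


def one_way_anova(
    data: pd.DataFrame,
    response: str,
    factor: str,
    transform_applied: str = "none",
) -> AnovaTable:
    """One-way ANOVA (between/within decomposition)."""
    sizes = data.groupby(factor)[response].size()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group {small.index[0]!r} has fewer than 2 observations")
    model = ols(f"Q('{response}') ~ C(Q('{factor}'))", data=data).fit()
    table = anova_lm(model, typ=1)
    table = table.rename(index=lambda s: s.replace(f"C(Q('{factor}'))", factor))
    return AnovaTable(
        table=table,
        df_resid=int(model.df_resid),
        transform_applied=transform_applied,
        ss_type=1,
    )


def standard_error(values) -> float:
    """Standard error of the mean: sample sd / √n."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def compare_cv(cv_manual, cv_automated) -> dict:
    """Replicate-variation comparison between methods (paired by individual)."""
    cv_manual = np.asarray(cv_manual, dtype=float)
    cv_automated = np.asarray(cv_automated, dtype=float)
    res = wilcoxon_signed_rank(cv_automated, cv_manual)
    return {
        "mean_cv_manual_pct": float(cv_manual.mean()),
        "mean_cv_automated_pct": float(cv_automated.mean()),
        "wilcoxon_statistic": res.statistic,
        "wilcoxon_p": res.p_value,
        "n_pairs": res.n_used,
        "n_zero_differences": res.n_zeros,
        "method": res.method,
    }
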