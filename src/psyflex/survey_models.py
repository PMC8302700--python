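"""Statistical battery for the survey arm: QC, adjusted regressions, contrasts.

* :func:`qc_screen` — Shapiro–Wilk normality check and 1.5·IQR outlier
  fences.
* :func:`fit_adjusted_model` — OLS of an outcome (composite schizotypy or a
  facet) on drug-use covariates ± demographics/diagnosis terms, reported
  with per-term slope/SE/t/p, residual df, plain and Cragg–Uhler pseudo-R²,
  and AIC. Complete-case per model, with the dropped count logged on the
  report.
* :func:`group_contrast` — Welch unequal-variance t with
  Welch–Satterthwaite df, one- or two-tailed, plus Cohen's d (pooled SD)
  with a 95% CI by noncentral-t inversion (normal approximation behind a
  flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import DegenerateInputError, SingularModelError, ValidationError


@dataclass(frozen=True)
class QCReport:
    shapiro_w: float
    shapiro_p: float
    outlier_indices: np.ndarray
    outlier_values: np.ndarray
    fences: tuple[float, float]
    n: int

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_indices)


def qc_screen(values) -> QCReport:
    """Normality and outlier screen of a numeric vector.

    Outliers are points outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; normality is
    the Shapiro–Wilk test.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValidationError("qc_screen needs at least 3 finite values")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask = (x < lo) | (x > hi)
    w, p = stats.shapiro(x)
    return QCReport(
        shapiro_w=float(w),
        shapiro_p=float(p),
        outlier_indices=np.where(mask)[0],
        outlier_values=x[mask],
        fences=(float(lo), float(hi)),
        n=len(x),
    )


@dataclass
class RegressionReport:
    """Tidy OLS report: one row per term plus model-level fit statistics."""

    terms: pd.DataFrame  # term, coef, se, t, p
    df_resid: int
    n: int
    n_dropped: int
    r_squared: float
    pseudo_r_squared_cu: float  # Cragg-Uhler / Nagelkerke from Gaussian likelihoods
    aic: float
    outcome: str
    degenerate: bool = False

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "coef"])

    def pvalue(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "p"])

    def summary(self) -> str:
        lines = [
            f"OLS: {self.outcome} ~ {' + '.join(t for t in self.terms['term'] if t != 'const')}",
            f"  n = {self.n} (dropped {self.n_dropped} incomplete), df_resid = {self.df_resid}",
            f"  R2 = {self.r_squared:.3f}, pseudo-R2 (Cragg-Uhler) = "
            f"{self.pseudo_r_squared_cu:.3f}, AIC = {self.aic:.2f}",
        ]
        if self.degenerate:
            lines.append("  WARNING: residual variance ~ 0 (degenerate fit)")
        with pd.option_context("display.float_format", "{:0.4f}".format):
            lines.append(self.terms.to_string(index=False))
        return "\n".join(lines)


def _collinear_terms(x: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns made redundant by earlier ones (pivoted QR)."""
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    return [names[j] for j in piv[rank:]]


def fit_adjusted_model(table: pd.DataFrame, outcome: str, predictors: list[str]) -> RegressionReport:
    """OLS of ``outcome`` on ``predictors`` with an intercept.

    Complete-case per model (incomplete rows dropped and counted). Raises
    :class:`SingularModelError` naming the collinear terms on rank
    deficiency; a residual variance of ~0 (e.g. regressing an outcome on
    itself) is flagged ``degenerate`` rather than raised.
    """
    import statsmodels.api as sm

    cols = [outcome] + list(predictors)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"table is missing columns {missing}")
    sub = table[cols].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    y = complete[outcome].to_numpy(float)
    x = sm.add_constant(complete[list(predictors)].to_numpy(float), has_constant="add")
    names = ["const"] + list(predictors)
    if len(complete) <= x.shape[1]:
        raise DegenerateInputError(
            f"{len(complete)} complete cases for {x.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_terms(x, names)
        raise SingularModelError(
            f"design matrix is rank deficient; collinear terms: {bad}", collinear_terms=bad
        )
    res = sm.OLS(y, x).fit()
    n = len(y)
    degenerate = bool(res.ssr / n < 1e-12 * max(1.0, float(np.var(y))) or res.ssr <= 0)
    # Cragg-Uhler (Nagelkerke) pseudo-R2 from Gaussian log likelihoods
    ll1 = float(res.llf)
    ll0 = float(sm.OLS(y, np.ones((n, 1))).fit().llf)
    r2_cs = 1.0 - np.exp((2.0 / n) * (ll0 - ll1))
    max_r2 = 1.0 - np.exp((2.0 / n) * ll0)
    # for a continuous outcome the null density can exceed 1 (max_r2 <= 0);
    # the normaliser is then dropped and Cox-Snell reported as-is
    pseudo_cu = float(r2_cs / max_r2) if max_r2 > 0 else float(r2_cs)
    terms = pd.DataFrame(
        {
            "term": names,
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    if degenerate and res.ssr <= 0:
        terms[["se", "t", "p"]] = np.nan
    return RegressionReport(
        terms=terms,
        df_resid=int(res.df_resid),
        n=n,
        n_dropped=n_dropped,
        r_squared=float(res.rsquared),
        pseudo_r_squared_cu=pseudo_cu,
        aic=float(res.aic),
        outcome=outcome,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class ContrastReport:
    """Welch two-sample contrast with Cohen's d and its 95% CI."""

    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    n_1: int
    n_2: int
    t: float
    df: float  # Welch-Satterthwaite (fractional)
    p: float
    tail: str
    cohen_d: float
    d_ci: tuple[float, float]
    labels: tuple = field(default=("group1", "group2"))

    def summary(self) -> str:
        return (
            f"{self.labels[0]} (n={self.n_1}): {self.mean_1:.3f} ± {self.sd_1:.3f}  vs  "
            f"{self.labels[1]} (n={self.n_2}): {self.mean_2:.3f} ± {self.sd_2:.3f}\n"
            f"Welch t({self.df:.1f}) = {self.t:.3f}, p ({self.tail}) = {self.p:.4g}, "
            f"Cohen's d [95% CI] = {self.cohen_d:.2f} [{self.d_ci[0]:.2f}, {self.d_ci[1]:.2f}]"
        )


def welch_satterthwaite_df(s1: float, n1: int, s2: float, n2: int) -> float:
    a, b = s1**2 / n1, s2**2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def cohen_d_ci(d: float, n1: int, n2: int, level: float = 0.95, method: str = "nct") -> tuple[float, float]:
    """Confidence interval for Cohen's d.

    ``method="nct"`` inverts the noncentral-t distribution of the pooled-SD
    t statistic (df = n1 + n2 − 2); ``"normal"`` uses the large-sample
    normal approximation of Var(d).
    """
    nt = n1 * n2 / (n1 + n2)
    df = n1 + n2 - 2
    t_obs = d * np.sqrt(nt)
    alpha = 1.0 - level
    if method == "normal":
        se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
        z = stats.norm.ppf(1 - alpha / 2)
        return (d - z * se, d + z * se)
    if method != "nct":
        raise ValueError(f"unknown CI method {method!r}")

    def lo_eq(nc):
        return stats.nct.sf(t_obs, df, nc) - alpha / 2

    def hi_eq(nc):
        return stats.nct.cdf(t_obs, df, nc) - alpha / 2

    span = abs(t_obs) + 10.0
    try:
        nc_lo = optimize.brentq(lo_eq, t_obs - span, t_obs + span, xtol=1e-8)
    except ValueError:
        nc_lo = t_obs - span
    try:
        nc_hi = optimize.brentq(hi_eq, t_obs - span, t_obs + span, xtol=1e-8)
    except ValueError:
        nc_hi = t_obs + span
    return (float(nc_lo / np.sqrt(nt)), float(nc_hi / np.sqrt(nt)))


def group_contrast(values, groups, tail: str = "two-sided", ci_method: str = "nct") -> ContrastReport:
    """Welch contrast of ``values`` between the two levels of ``groups``.

    Levels are ordered by sorted label; ``tail="greater"`` tests whether
    the first level's mean exceeds the second's. Cohen's d uses the pooled
    SD and is positive when the first level is higher.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {levels}")
    x1 = values[groups == levels[0]]
    x2 = values[groups == levels[1]]
    if len(x1) < 2 or len(x2) < 2:
        raise DegenerateInputError("each group needs n >= 2")
    n1, n2 = len(x1), len(x2)
    m1, m2 = x1.mean(), x2.mean()
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    df = welch_satterthwaite_df(s1, n1, s2, n2)
    alternative = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[tail]
    t, p = stats.ttest_ind(x1, x2, equal_var=False, alternative=alternative)
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    d = float((m1 - m2) / sp) if sp > 0 else 0.0
    ci = cohen_d_ci(d, n1, n2, method=ci_method) if sp > 0 else (0.0, 0.0)
    return ContrastReport(
        mean_1=float(m1),
        mean_2=float(m2),
        sd_1=float(s1),
        sd_2=float(s2),
        n_1=n1,
        n_2=n2,
        t=float(t),
        df=float(df),
        p=float(p),
        tail=tail,
        cohen_d=d,
        d_ci=(float(ci[0]), float(ci[1])),
        labels=(str(levels[0]), str(levels[1])),
    )
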