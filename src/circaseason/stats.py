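"""Seasonal comparisons and sigma-restricted general linear models.

Two layers:

* :func:`seasonal_anova` — one-way ANOVA across seasons with Tukey HSD
  post-hoc contrasts (studentized-range), per-group Shapiro-Wilk normality
  annotation and an optional Kruskal-Wallis fallback.

* :class:`SigmaRestrictedGLM` / :func:`fit_glm` — multivariable ANCOVA in
  the sigma-restricted (effects-coding) parameterization: continuous
  predictors are z-standardized, binary factors coded -1/+1, and season
  enters by default as a single ordered numeric contrast
  (winter < spring < summer).  Per term the table reports the standardized
  beta with 95% CI, the Type-III (partial) F and p, partial eta-squared
  = SS_term / (SS_term + SS_residual) = F*df1 / (F*df1 + df2), and
  observed power — the power of the term's F test at the sample-estimated
  noncentrality ncp = F_obs * df1 and alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .series import SEASONS

log = logging.getLogger(__name__)

__all__ = ["ComparisonResult", "GLMResult", "SigmaRestrictedGLM",
           "seasonal_anova", "fit_glm", "observed_power", "partial_eta_squared"]

SEASON_ORDER = {"winter": 0, "spring": 1, "summer": 2, "autumn": 3}


# ----------------------------------------------------------------------
# ANOVA / post hoc
# ----------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str
    statistic: float
    df: tuple[int, int]
    p: float
    posthoc: pd.DataFrame | None = None       # pair, difference, p_adj
    normality: pd.DataFrame | None = None     # group, W, p
    kruskal: tuple[float, float] | None = None  # (H, p) when requested


def seasonal_anova(cohort: pd.DataFrame, response: str, group: str = "season",
                   posthoc: bool = True, kruskal: bool = False) -> ComparisonResult:
    """One-way ANOVA of `response` across the levels of `group`.

    Reports the F statistic with (k-1, N-k) df, Tukey HSD adjusted p for
    all group pairs, and Shapiro-Wilk W/p per group as a normality
    annotation.  With every observation identical, F = 0 is reported and
    the post hoc is skipped.
    """
    data = cohort[[group, response]].dropna()
    levels = [lv for lv in SEASONS if lv in set(data[group])] or sorted(set(data[group]))
    groups = [data.loc[data[group] == lv, response].to_numpy(float) for lv in levels]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 observations each")
    N, k = sum(len(g) for g in groups), len(groups)

    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0.0:
        return ComparisonResult(test="anova", statistic=0.0, df=(k - 1, N - k), p=1.0)

    f_stat, p = stats.f_oneway(*groups)

    norm_rows = []
    for lv, g in zip(levels, groups):
        if len(g) >= 3 and np.ptp(g) > 0:
            w, wp = stats.shapiro(g)
        else:
            w, wp = np.nan, np.nan
        norm_rows.append({"group": lv, "W": w, "p": wp})

    ph = None
    if posthoc:
        res = stats.tukey_hsd(*groups)
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "pair": f"{levels[i]} vs {levels[j]}",
                    "difference": float(np.mean(groups[i]) - np.mean(groups[j])),
                    "p_adj": float(res.pvalue[i, j]),
                })
        ph = pd.DataFrame(rows)

    kw = None
    if kruskal:
        h, hp = stats.kruskal(*groups)
        kw = (float(h), float(hp))

    return ComparisonResult(test="anova", statistic=float(f_stat), df=(k - 1, N - k),
                            p=float(p), posthoc=ph,
                            normality=pd.DataFrame(norm_rows), kruskal=kw)


# ----------------------------------------------------------------------
# GLM
# ----------------------------------------------------------------------

def partial_eta_squared(F: float, df1: int, df2: int) -> float:
    """partial eta^2 = F*df1 / (F*df1 + df2)."""
    if not np.isfinite(F):
        return 1.0
    return F * df1 / (F * df1 + df2)


def observed_power(F: float, df1: int, df2: int, alpha: float = 0.05) -> float:
    """Power of the F(df1, df2) test at the sample noncentrality ncp = F*df1."""
    if not np.isfinite(F):
        return 1.0
    fcrit = stats.f.ppf(1.0 - alpha, df1, df2)
    power = float(stats.ncf.sf(fcrit, df1, df2, F * df1))
    if np.isnan(power):  # ncf overflows at extreme noncentrality
        return 1.0 if F * df1 > 100 else np.nan
    return power


@dataclass
class GLMResult:
    """Per-term effect table of one model specification."""

    table: pd.DataFrame       # term, beta, ci_low, ci_high, coef, F, p, df1, df2,
                              # partial_eta_sq, observed_power
    n: int
    df_resid: int
    r_squared: float
    coding: str = "sigma_restricted"
    response: str = ""
    dropped_rows: int = 0
    model: object = field(default=None, repr=False)


def _code_term(col: pd.Series, term: str, season_coding: str):
    """Return (list of column arrays, list of names, is_categorical)."""
    if term == "season":
        if season_coding == "ordered":
            order = col.map(SEASON_ORDER)
            if order.isna().any():
                raise ValueError(f"unknown season levels {set(col[order.isna()])}")
            return [order.to_numpy(float)], [term], False
        levels = [lv for lv in SEASONS if lv in set(col)]
        # sigma-restricted: k-1 columns, last level coded -1 everywhere
        cols, names = [], []
        for lv in levels[:-1]:
            v = np.where(col == lv, 1.0, np.where(col == levels[-1], -1.0, 0.0))
            cols.append(v)
            names.append(f"{term}[{lv}]")
        return cols, names, True
    if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
        levels = sorted(set(col))
        if len(levels) != 2:
            raise ValueError(f"factor {term!r} must be binary, has levels {levels}")
        return [np.where(col == levels[1], 1.0, -1.0)], [term], True
    return [col.to_numpy(float)], [term], False


class SigmaRestrictedGLM:
    """Multivariable ANCOVA with sigma-restricted parameterization.

    Parameters
    ----------
    response : str
        Response column (analysed as given; pass log2 expression for
        fold-change models).
    terms : sequence of str
        Predictor columns.  ``season`` is recognised specially.
    season_coding : {"ordered", "categorical"}
        ``ordered`` codes winter < spring < summer (< autumn) as one
        numeric df; ``categorical`` uses k-1 effect-coded columns.
    seasons : sequence of str or None
        Restrict to these seasons before fitting (e.g. omit autumn).
    standardize_response : bool, default True
        z-score the response so betas are fully standardized.

    Attributes
    ----------
    result_ : GLMResult
    """

    def __init__(self, response: str, terms, season_coding: str = "ordered",
                 seasons=None, standardize_response: bool = True,
                 alpha: float = 0.05):
        self.response = response
        self.terms = list(terms)
        self.season_coding = season_coding
        self.seasons = list(seasons) if seasons is not None else None
        self.standardize_response = standardize_response
        self.alpha = alpha

    def get_params(self, deep=True):  # sklearn-compatible introspection
        return {"response": self.response, "terms": self.terms,
                "season_coding": self.season_coding, "seasons": self.seasons,
                "standardize_response": self.standardize_response,
                "alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, cohort: pd.DataFrame):
        data = cohort
        if self.seasons is not None and "season" in data.columns:
            data = data[data["season"].isin(self.seasons)]
        cols = [self.response] + [t for t in self.terms]
        n_before = len(data)
        data = data.dropna(subset=[c for c in cols if c in data.columns])
        dropped = n_before - len(data)
        if dropped:
            log.info("fit_glm: %d incomplete row(s) dropped listwise", dropped)
        if len(data) < len(self.terms) + 2:
            raise ValueError("too few complete-case rows for the requested terms")

        blocks, names, spans = [], [], []
        for term in self.terms:
            if term not in data.columns:
                raise KeyError(f"term {term!r} not in cohort table")
            arrs, nms, is_factor = _code_term(data[term], term, self.season_coding)
            std_arrs = []
            for a in arrs:
                sd = a.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"predictor {term!r} has zero variance")
                # continuous predictors are z-scored; -1/+1 factor codes are
                # the sigma-restricted parameterization and stay as coded
                std_arrs.append(a if is_factor else (a - a.mean()) / sd)
            spans.append((term, len(blocks), len(blocks) + len(std_arrs)))
            blocks.extend(std_arrs)
            names.extend(nms)

        X = np.column_stack([np.ones(len(data))] + blocks)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design; collinear terms among {self.terms}")

        y_raw = data[self.response].to_numpy(float)
        sd_y = y_raw.std(ddof=1)
        y = (y_raw - y_raw.mean()) / sd_y if self.standardize_response and sd_y > 0 else y_raw

        ols = sm.OLS(y, X).fit()
        n = int(ols.nobs)
        df2 = int(ols.df_resid)

        rows = []
        for term, lo, hi in spans:
            df1 = hi - lo
            idx = np.arange(1 + lo, 1 + hi)
            if df1 == 1:
                t_val = ols.tvalues[idx[0]]
                F = float(t_val**2)
                p = float(stats.f.sf(F, 1, df2))
                beta = float(ols.params[idx[0]])
                half = stats.t.ppf(1 - self.alpha / 2, df2) * float(ols.bse[idx[0]])
                ci_lo, ci_hi = beta - half, beta + half
                coef = beta * (sd_y if self.standardize_response and sd_y > 0 else 1.0)
            else:
                R = np.zeros((df1, X.shape[1]))
                for r_i, c_i in enumerate(idx):
                    R[r_i, c_i] = 1.0
                wt = ols.f_test(R)
                F, p = float(wt.fvalue), float(wt.pvalue)
                beta = ci_lo = ci_hi = coef = np.nan
            rows.append({
                "term": term, "beta": beta, "ci_low": ci_lo, "ci_high": ci_hi,
                "coef": coef, "F": F, "p": p, "df1": df1, "df2": df2,
                "partial_eta_sq": partial_eta_squared(F, df1, df2),
                "observed_power": observed_power(F, df1, df2, self.alpha),
            })

        self.result_ = GLMResult(
            table=pd.DataFrame(rows), n=n, df_resid=df2,
            r_squared=float(ols.rsquared), response=self.response,
            dropped_rows=dropped, model=ols,
        )
        return self


def fit_glm(cohort: pd.DataFrame, response: str, terms,
            season_coding: str = "ordered", seasons=None,
            standardize_response: bool = True) -> GLMResult:
    """Fit a sigma-restricted GLM; see :class:`SigmaRestrictedGLM`.

    The returned table carries, per term: fully standardized beta with its
    95% CI, Type-III F and p, partial eta^2 and observed power; ``coef``
    is the per-SD-of-predictor effect on the unstandardized response scale.
    """
    return SigmaRestrictedGLM(response=response, terms=terms,
                              season_coding=season_coding, seasons=seasons,
                              standardize_response=standardize_response,
                              ).fit(cohort).result_
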