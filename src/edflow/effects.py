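"""Interaction regressions, ANOVA and standardized-effect summaries for
full-factorial response tables.

Models are fit on raw factor units (capacity counts), matching how the
staffing equations are reported; a coded (−1/0/+1) parameterization is
available via ``coded=True``.  Each regression term is a product of
factor columns; per-term F tests are partial (drop-one) tests, which for
single-degree-of-freedom terms equal the squared t statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RegressionFit",
    "AnovaTable",
    "EffectSummary",
    "SingularDesignError",
    "standard_terms",
    "fit_ols",
    "anova",
    "effect_summaries",
    "format_equation",
    "format_p",
]

Term = Tuple[str, ...]


class SingularDesignError(ValueError):
    """Design matrix is rank-deficient for the requested terms."""


def standard_terms(factors: Sequence[str], three_way: bool = False) -> List[Term]:
    """Main effects + all 2-way interactions (+ the 3-way if asked)."""
    factors = list(factors)
    terms: List[Term] = [(f,) for f in factors]
    terms += [tuple(c) for c in itertools.combinations(factors, 2)]
    if three_way:
        terms += [tuple(c) for c in itertools.combinations(factors, 3)]
    return terms


def term_name(term: Term) -> str:
    return "*".join(term)


def _design_matrix(
    data: pd.DataFrame, terms: Sequence[Term], coded: bool
) -> pd.DataFrame:
    cols = {}
    work = data.copy()
    factors = sorted({f for t in terms for f in t})
    if coded:
        for f in factors:
            lo, hi = work[f].min(), work[f].max()
            if hi == lo:
                raise SingularDesignError(f"factor {f!r} is constant")
            work[f] = (work[f] - (lo + hi) / 2.0) / ((hi - lo) / 2.0)
    for term in terms:
        col = np.ones(len(work))
        for f in term:
            col = col * work[f].to_numpy(dtype=float)
        cols[term_name(term)] = col
    X = pd.DataFrame(cols, index=data.index)
    X.insert(0, "Intercept", 1.0)
    return X


def _aliased_terms(X: pd.DataFrame) -> List[str]:
    """Columns that do not increase the rank when added left to right."""
    aliased = []
    acc = np.empty((len(X), 0))
    rank = 0
    for name in X.columns:
        cand = np.column_stack([acc, X[name].to_numpy()])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            acc, rank = cand, r
        else:
            aliased.append(name)
    return aliased


@dataclass
class RegressionFit:
    """OLS fit of a factorial response model.

    ``r2`` and ``adj_r2`` are percentages, as the model summaries are
    conventionally reported.
    """

    response: str
    terms: List[Term]
    coef: Dict[str, float]
    se: Dict[str, float]
    tvalues: Dict[str, float]
    pvalues: Dict[str, float]
    r2: float
    adj_r2: float
    df_resid: int
    ss_resid: float
    ss_total: float
    nobs: int
    coded: bool = False
    model_f: float = float("nan")
    model_p: float = float("nan")

    @property
    def intercept(self) -> float:
        return self.coef["Intercept"]


def fit_ols(
    responses: pd.DataFrame,
    terms: Sequence[Term],
    response: str,
    coded: bool = False,
    point_means: bool = False,
) -> RegressionFit:
    """Least-squares fit of ``response`` on the given product terms.

    Parameters
    ----------
    responses : DataFrame
        One row per (design point, replication) with factor columns and
        the response column.
    terms : sequence of tuples
        Each term is a tuple of factor names; the product of those
        columns enters the design matrix.  Use :func:`standard_terms`.
    coded : bool
        Recode factors onto −1/0/+1 before fitting.
    point_means : bool
        Average replications per design point first (coefficients are
        unchanged on balanced designs; R² is not).

    Raises
    ------
    SingularDesignError
        If the term set is not estimable on the distinct design points.
    """
    terms = [tuple(t) for t in terms]
    if response not in responses.columns:
        raise KeyError(f"response column {response!r} not in table")
    data = responses
    factors = sorted({f for t in terms for f in t})
    if point_means:
        data = data.groupby(factors, as_index=False)[response].mean()

    X = _design_matrix(data, terms, coded)
    distinct = X.drop_duplicates()
    if np.linalg.matrix_rank(distinct.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient design; aliased terms: {_aliased_terms(distinct)}"
        )

    y = data[response].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # degenerate designs (zero residual/total SS) emit 0/0 warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(y, X).fit()
        model_f = float(res.fvalue) if res.df_resid > 0 else float("inf")
        model_p = float(res.f_pvalue) if res.df_resid > 0 else float("nan")
        extracted = dict(
            coef=dict(res.params),
            se=dict(res.bse),
            tvalues=dict(res.tvalues),
            pvalues=dict(res.pvalues),
            r2=float(res.rsquared) * 100.0,
            adj_r2=float(res.rsquared_adj) * 100.0,
            df_resid=int(res.df_resid),
            ss_resid=float(res.ssr),
            ss_total=float(res.centered_tss),
            nobs=int(res.nobs),
        )

    return RegressionFit(
        response=response,
        terms=list(terms),
        coded=coded,
        model_f=model_f,
        model_p=model_p,
        **extracted,
    )


@dataclass
class AnovaTable:
    """Per-term partial F tests plus the model-level test."""

    table: pd.DataFrame  # columns: term, df, sum_sq, F, p
    model_f: float
    model_p: float
    df_resid: int
    ms_resid: float
    degenerate: bool = False  # zero residual variance: F undefined/inf


def anova(fit: RegressionFit) -> AnovaTable:
    """Partial (drop-one) F test per term; equals t² for 1-df terms.

    A saturated or noiseless fit (zero residual mean square) yields
    infinite F statistics and is flagged ``degenerate`` rather than
    raising.
    """
    if fit.df_resid <= 0:
        raise ValueError("saturated model: zero residual degrees of freedom")
    ms_resid = fit.ss_resid / fit.df_resid
    # residual variance at numerical zero relative to the response scale
    floor = 1e-12 * max(fit.ss_total, fit.nobs * (1.0 + fit.coef["Intercept"] ** 2))
    degenerate = not np.isfinite(ms_resid) or fit.ss_resid <= floor
    from scipy import stats

    rows = []
    for term in fit.terms:
        name = term_name(term)
        t = fit.tvalues[name]
        if degenerate or not np.isfinite(t):
            f_stat, p = float("inf"), 0.0 if not degenerate else float("nan")
        else:
            f_stat = t * t
            p = float(stats.f.sf(f_stat, 1, fit.df_resid))
        rows.append(
            {
                "term": name,
                "df": 1,
                "sum_sq": f_stat * ms_resid if np.isfinite(f_stat) else float("nan"),
                "F": f_stat,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    return AnovaTable(
        table=table,
        model_f=fit.model_f,
        model_p=fit.model_p,
        df_resid=fit.df_resid,
        ms_resid=ms_resid,
        degenerate=degenerate,
    )


@dataclass
class EffectSummary:
    """Plot-ready effect tables: Pareto of |t|, level means, cell means."""

    pareto: pd.DataFrame  # columns: term, standardized_effect (non-increasing)
    main_effects: Dict[str, pd.Series]  # factor -> level means
    interactions: Dict[Tuple[str, str], pd.DataFrame]  # pair -> cell-mean pivot
    grand_mean: float


def effect_summaries(
    responses: pd.DataFrame, fit: RegressionFit
) -> EffectSummary:
    """Standardized effects (|t|), main-effect and interaction means.

    Warns (and falls back to weighted means) when the design is not
    balanced across factor levels.
    """
    factors = sorted({f for t in fit.terms for f in t})
    y = fit.response

    counts = responses.groupby(factors).size()
    if counts.nunique() > 1:
        warnings.warn(
            "unbalanced design: level means are frequency-weighted", UserWarning
        )

    grand = float(responses[y].mean())
    flat = fit.ss_total <= 1e-12 * fit.nobs * (1.0 + grand * grand)

    def effect(t):
        if flat:
            return 0.0
        value = abs(fit.tvalues[term_name(t)])
        return value if np.isfinite(value) else 0.0

    pareto = pd.DataFrame(
        {
            "term": [term_name(t) for t in fit.terms],
            "standardized_effect": [effect(t) for t in fit.terms],
        }
    ).sort_values("standardized_effect", ascending=False, kind="mergesort", ignore_index=True)

    main_effects = {f: responses.groupby(f)[y].mean() for f in factors}
    interactions = {
        (a, b): responses.pivot_table(index=a, columns=b, values=y, aggfunc="mean")
        for a, b in itertools.combinations(factors, 2)
    }
    return EffectSummary(
        pareto=pareto,
        main_effects=main_effects,
        interactions=interactions,
        grand_mean=grand,
    )


def format_p(p: float, floor: float = 1e-3) -> str:
    """Render a p value, reporting tiny values as '<0.001'."""
    if not np.isfinite(p):
        return "nan"
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3f}"


def format_equation(fit: RegressionFit, lhs: Optional[str] = None) -> str:
    """Render the fitted equation in report style, e.g.
    ``LOS = -35.0 + 15.04 nurses + ... - 1.062 beds*triage``."""
    lhs = lhs or fit.response
    parts = [f"{fit.intercept:.4g}"]
    for term in fit.terms:
        name = term_name(term)
        c = fit.coef[name]
        sign = "+" if c >= 0 else "-"
        parts.append(f"{sign} {abs(c):.4g} {name}")
    return f"{lhs} = " + " ".join(parts)
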