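"""Lande–Arnold selection-gradient estimation and GLM-based significance tests.

The workflow mirrors standard phenotypic selection analysis on a single
trait (fork length at maturity):

* trait values are standardized to mean 0 / SD 1 *within the analysed
  subset* (a year, a tactic, a year x tactic cell, or the pooled data),
* relative fitness ``w`` is absolute reproductive success divided by the
  subset mean reproductive success,
* the directional gradient ``beta`` is the OLS slope of ``w`` on
  standardized length,
* the quadratic gradient ``gamma`` is **twice** the OLS coefficient on
  squared standardized length in a model that retains the linear term
  (its SE is doubled along with it),
* statistical significance comes from Poisson log-link GLMs of absolute
  reproductive success, with likelihood-ratio (analysis-of-deviance)
  chi-square tests of nested models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConfigError, DegenerateDataError, InsufficientDataError
from .pedigree import Pedigree, TACTICS

__all__ = [
    "SelectionGradients", "DevianceTest", "FullGlmFit",
    "standardize", "linear_gradient", "quadratic_gradient",
    "fit_poisson_glm", "deviance_term_test", "interaction_scan", "selection_table",
]

_STD_TOL = 1e-10


def _frame(data: Union[Pedigree, pd.DataFrame]) -> pd.DataFrame:
    return data.frame if isinstance(data, Pedigree) else data


@dataclass(frozen=True)
class SelectionGradients:
    """Linear (beta) and quadratic (gamma) gradients for one subset.

    ``model`` records whether beta came from the linear-only regression or
    jointly from the quadratic model; gamma is NaN for linear-only fits.
    """

    beta: float
    se_beta: float
    gamma: float
    se_gamma: float
    n: int
    label: str = ""
    model: str = "linear"


@dataclass(frozen=True)
class DevianceTest:
    """Likelihood-ratio (analysis-of-deviance) test of one dropped term."""

    term: str
    chi_sq: float
    df: int
    p: float
    n: int


@dataclass(frozen=True)
class FullGlmFit:
    """A fitted Poisson log-link GLM of absolute reproductive success."""

    formula: str
    params: pd.Series
    deviance: float
    llf: float
    converged: bool
    n: int
    k: int
    exog_names: tuple


def standardize(data: Union[Pedigree, pd.DataFrame]) -> pd.DataFrame:
    """Standardize length and compute relative fitness within one subset.

    Returns a copy of the subset with ``std_length`` ((length - mean)/SD,
    sample SD), ``std_length_sq`` and ``rel_fitness`` (rs / mean rs)
    columns.  The subset's own mean and SD are always used — pooled
    analyses pass the pooled subset, never averages of per-subset values.
    """
    df = _frame(data)
    if df.empty:
        raise DegenerateDataError("cannot standardize an empty subset")
    length = df["length_mm"].astype(float)
    rs = df["rs"].astype(float)
    sd = length.std(ddof=1)
    if not sd > 0 or not np.isfinite(sd):
        raise DegenerateDataError("length SD is zero (all lengths equal); standardization undefined")
    mean_rs = rs.mean()
    if not mean_rs > 0:
        raise DegenerateDataError("mean reproductive success is zero; relative fitness undefined")
    out = df.copy()
    # plain numpy dtypes: the formula machinery cannot use nullable Int64
    out["rs"] = rs.astype(int)
    if "year" in out.columns and out["year"].notna().all():
        out["year"] = out["year"].astype(int)
    if "tactic" in out.columns:
        out["tactic"] = out["tactic"].astype(object)
    out["std_length"] = (length - length.mean()) / sd
    out["std_length_sq"] = out["std_length"] ** 2
    out["rel_fitness"] = rs / mean_rs
    assert abs(out["std_length"].mean()) < _STD_TOL
    assert abs(out["rel_fitness"].mean() - 1.0) < _STD_TOL
    return out


def _ols(y: np.ndarray, X: np.ndarray):
    res = sm.OLS(y, X).fit()
    return res.params, res.bse


def linear_gradient(records: pd.DataFrame, label: str = "") -> SelectionGradients:
    """Directional gradient: OLS slope of relative fitness on standardized length."""
    x = np.asarray(records["std_length"], dtype=float)
    w = np.asarray(records["rel_fitness"], dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"linear gradient needs >= 3 records, got {len(x)}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("standardized length is constant")
    params, bse = _ols(w, sm.add_constant(x))
    return SelectionGradients(
        beta=float(params[1]), se_beta=float(bse[1]),
        gamma=float("nan"), se_gamma=float("nan"),
        n=len(x), label=label, model="linear",
    )


def quadratic_gradient(records: pd.DataFrame, label: str = "") -> SelectionGradients:
    """Quadratic gradient via the doubling convention.

    Fits ``w ~ 1 + x + x^2`` and reports gamma = 2 x the quadratic
    coefficient with its SE doubled as well; beta here is the linear
    coefficient of the same joint model.
    """
    x = np.asarray(records["std_length"], dtype=float)
    w = np.asarray(records["rel_fitness"], dtype=float)
    if len(x) < 4:
        raise InsufficientDataError(f"quadratic gradient needs >= 4 records, got {len(x)}")
    X = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDataError("design matrix for the quadratic model is rank-deficient")
    params, bse = _ols(w, X)
    return SelectionGradients(
        beta=float(params[1]), se_beta=float(bse[1]),
        gamma=2.0 * float(params[2]), se_gamma=2.0 * float(bse[2]),
        n=len(x), label=label, model="quadratic",
    )


def fit_poisson_glm(
    records: pd.DataFrame,
    formula_rhs: str = "std_length",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> FullGlmFit:
    """Maximum-likelihood Poisson log-link GLM of absolute reproductive success.

    ``formula_rhs`` is the right-hand side of a patsy formula over the
    record columns (e.g. ``"std_length + std_length_sq"`` or the full
    tactic x year interaction model).  Non-convergence within ``maxiter``
    IRLS iterations is flagged, not silently ignored.
    """
    rs = np.asarray(records["rs"], dtype=float)
    if np.any(rs < 0) or np.any(rs != np.floor(rs)):
        raise ConfigError("rs must be nonnegative integers for the Poisson model")
    formula = f"rs ~ {formula_rhs}"
    model = smf.glm(formula, data=records, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=tol)
    if not np.all(np.isfinite(res.params)):
        raise DegenerateDataError(f"unbounded likelihood (separation?) fitting {formula}")
    return FullGlmFit(
        formula=formula,
        params=res.params,
        deviance=float(res.deviance),
        llf=float(res.llf),
        converged=bool(res.converged),
        n=int(res.nobs),
        k=len(res.params),
        exog_names=tuple(model.exog_names),
    )


def deviance_term_test(full: FullGlmFit, reduced: FullGlmFit, term: str = "") -> DevianceTest:
    """Analysis-of-deviance chi-square test of ``full`` against a nested ``reduced``."""
    if full.n != reduced.n:
        raise ConfigError("models were fit to different numbers of records")
    if not set(reduced.exog_names) <= set(full.exog_names):
        raise ConfigError(
            f"models are not nested: {set(reduced.exog_names) - set(full.exog_names)} "
            "only in the reduced model"
        )
    df = full.k - reduced.k
    chi = max(0.0, reduced.deviance - full.deviance)
    if df == 0:
        return DevianceTest(term=term, chi_sq=0.0, df=0, p=1.0, n=full.n)
    return DevianceTest(term=term, chi_sq=chi, df=df, p=float(stats.chi2.sf(chi, df)), n=full.n)


# term fragments of the full reproductive-success model
_X, _Q, _T, _Y = "std_length", "std_length_sq", "C(tactic)", "C(year)"
_BASE_TERMS = [
    _X, _Q, _T, _Y,
    f"{_X}:{_T}", f"{_Q}:{_T}", f"{_X}:{_Y}", f"{_Q}:{_Y}", f"{_T}:{_Y}",
]
_L3 = f"{_X}:{_T}:{_Y}"
_Q3 = f"{_Q}:{_T}:{_Y}"

#: Fixed output order of :func:`interaction_scan` (term labels).
INTERACTION_SCAN_ORDER = (
    "StdLength2:Tactic:Year | full model",
    "StdLength:Tactic:Year | full model",
    "StdLength:Tactic:Year | quadratic 3-way removed",
    "StdLength:Tactic | no 3-way interactions",
    "StdLength2:Tactic | no 3-way interactions",
    "StdLength:Year | no 3-way interactions",
    "StdLength2:Year | no 3-way interactions",
)


def interaction_scan(p: Union[Pedigree, pd.DataFrame]) -> list[DevianceTest]:
    """Backward testing sequence for year/tactic heterogeneity of selection.

    Starting from the full Poisson GLM of reproductive success on
    standardized length, its square, tactic, year and all interactions
    involving length, the sequence (1) tests each 3-way interaction against
    the full model, (2) drops the quadratic 3-way and retests the linear
    3-way, then (3) drops both 3-ways and tests each 2-way interaction
    involving length by single-term deletion.  Lengths are standardized on
    the pooled input.  Output order is fixed; see
    :data:`INTERACTION_SCAN_ORDER`.
    """
    records = standardize(p)
    for factor in ("year", "tactic"):
        if records[factor].nunique() < 2:
            raise DegenerateDataError(
                f"interaction scan needs >= 2 levels of {factor}, got {records[factor].nunique()}"
            )

    def fit(terms: Sequence[str]) -> FullGlmFit:
        return fit_poisson_glm(records, " + ".join(terms))

    m_full = fit(_BASE_TERMS + [_L3, _Q3])
    m_no_q3 = fit(_BASE_TERMS + [_L3])
    m_no_l3 = fit(_BASE_TERMS + [_Q3])
    m_no_3 = fit(_BASE_TERMS)

    tests = [
        deviance_term_test(m_full, m_no_q3, INTERACTION_SCAN_ORDER[0]),
        deviance_term_test(m_full, m_no_l3, INTERACTION_SCAN_ORDER[1]),
        deviance_term_test(m_no_q3, m_no_3, INTERACTION_SCAN_ORDER[2]),
    ]
    two_ways = [f"{_X}:{_T}", f"{_Q}:{_T}", f"{_X}:{_Y}", f"{_Q}:{_Y}"]
    for label, term in zip(INTERACTION_SCAN_ORDER[3:], two_ways):
        reduced = fit([t for t in _BASE_TERMS if t != term])
        tests.append(deviance_term_test(m_no_3, reduced, label))
    return tests


_TABLE_COLUMNS = [
    "year", "tactic", "n",
    "beta", "se_beta", "chi_sq_beta", "df_beta", "p_beta",
    "gamma", "se_gamma", "chi_sq_gamma", "df_gamma", "p_gamma",
    "note",
]


def _na_row(year, tactic, n, note) -> dict:
    row = {c: np.nan for c in _TABLE_COLUMNS}
    row.update({"year": year, "tactic": tactic, "n": n, "note": note})
    return row


def selection_table(p: Union[Pedigree, pd.DataFrame], min_n: int = 5) -> pd.DataFrame:
    """Per (year x tactic, plus pooled) gradient table.

    For each subset: beta and its SE from the linear-only OLS; gamma and
    its doubled SE from the joint quadratic OLS; chi-square columns are
    analysis-of-deviance tests of the linear term (``rs ~ x`` vs intercept)
    and of the quadratic term (``rs ~ x + x^2`` vs ``rs ~ x``) under the
    Poisson log-link GLM.  Pooled rows re-standardize on the pooled subset.
    Subsets that are empty or too small/degenerate become NA rows with the
    reason recorded in ``note``.
    """
    df = _frame(p)
    years: list = ["all"] + sorted(df["year"].dropna().unique().tolist())
    tactics: list = ["all"] + [t for t in TACTICS if t in set(df["tactic"])]
    rows = []
    for year in years:
        for tactic in tactics:
            sub = df
            if year != "all":
                sub = sub[sub["year"].eq(year)]
            if tactic != "all":
                sub = sub[sub["tactic"].eq(tactic)]
            label = f"{year}/{tactic}"
            if len(sub) < min_n:
                rows.append(_na_row(year, tactic, len(sub), f"fewer than {min_n} individuals"))
                continue
            try:
                recs = standardize(sub)
                lin = linear_gradient(recs, label)
                quad = quadratic_gradient(recs, label)
                m0 = fit_poisson_glm(recs, "1")
                m1 = fit_poisson_glm(recs, _X)
                m2 = fit_poisson_glm(recs, f"{_X} + {_Q}")
                t_beta = deviance_term_test(m1, m0, "StdLength")
                t_gamma = deviance_term_test(m2, m1, "StdLength2")
            except (DegenerateDataError, InsufficientDataError) as exc:
                rows.append(_na_row(year, tactic, len(sub), str(exc)))
                continue
            rows.append({
                "year": year, "tactic": tactic, "n": len(sub),
                "beta": lin.beta, "se_beta": lin.se_beta,
                "chi_sq_beta": t_beta.chi_sq, "df_beta": t_beta.df, "p_beta": t_beta.p,
                "gamma": quad.gamma, "se_gamma": quad.se_gamma,
                "chi_sq_gamma": t_gamma.chi_sq, "df_gamma": t_gamma.df, "p_gamma": t_gamma.p,
                "note": "",
            })
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
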