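"""Parent–offspring regression heritability with unequal-variance corrections.

Narrow-sense heritability from a *single* parent–offspring regression is
``h² = 2·b_op`` where ``b_op`` is the slope of mean offspring phenotype on
one parent's phenotype.  When the parent's and offspring's tactic classes
differ in phenotypic variance, the doubling is rescaled by the ratio of
standard deviations, ``h² = 2·b_op·(σ_p/σ_o)`` (Falconer's correction), and
the null slope corresponding to ``h² = 1`` moves from 0.5 to
``0.5/(σ_p/σ_o)``.  Two hypothesis tests accompany every estimate: a t test
of slope = 0 (h² = 0) and an F test of slope = the h² = 1 null value.

The 3×3 grid crosses parent tactic (dam, jack sire, hooknose sire) with
offspring tactic (daughter, jack son, hooknose son); each offspring
contributes to both its dam-cell and its sire-cell regressions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConfigError, DegenerateDataError, InsufficientDataError
from .pedigree import Pedigree, TACTICS

__all__ = [
    "VarianceComparison", "HeritabilityEstimate", "OffspringInteractionFit",
    "bartlett_test", "variance_ratio_test", "parent_offspring_regression",
    "heritability_from_slope", "test_slope", "heritability_grid",
    "offspring_interaction_model",
]

CI_Z = 1.96  # normal 95% multiplier; the CI half-width is 1.96 * (2*se*corr)


@dataclass(frozen=True)
class VarianceComparison:
    """Bartlett homogeneity test plus all pairwise variance-ratio F tests."""

    bartlett_k2: float
    bartlett_df: int
    bartlett_p: float
    #: mapping (group_a, group_b) -> dict(F, df1, df2, p); F = var(a)/var(b)
    pairwise: Mapping[tuple, dict]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """One cell of the parent-tactic × offspring-tactic heritability grid."""

    parent_tactic: str
    offspring_tactic: str
    b_op: float
    se_slope: float
    n_families: int
    sigma_p: float
    sigma_o: float
    corrected: bool
    correction: float          # 1 if variances homogeneous, else sigma_p/sigma_o
    h2: float                  # 2 * b_op * correction
    ci95: float                # 1.96 * 2 * se_slope * correction (half-width)
    null_slope_h2_one: float   # 0.5 / correction
    t_zero: float
    p_zero: float
    F_one: float
    p_one: float


@dataclass(frozen=True)
class OffspringInteractionFit:
    """OLS fit of offspring length on dam length, sire length, offspring
    tactic and the two length × tactic interactions, with sequential
    (type-I) F tests in the model's term order."""

    params: pd.Series
    anova: pd.DataFrame  # index = term, columns = sum_sq, df, F, p
    n: int
    df_resid: int


def _lengths(x: Iterable) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.ndim != 1:
        raise ConfigError("each group must be a 1-d collection of lengths")
    return arr


def variance_ratio_test(a: Iterable, b: Iterable) -> tuple[float, int, int, float]:
    """Two-sided F test for equality of two variances.

    Returns ``(F, df1, df2, p)`` with ``F = var(a)/var(b)`` (sample
    variances), ``df = n−1`` each, and two-sided p value.  Swapping the
    groups inverts F and swaps the dfs but keeps p.
    """
    xa, xb = _lengths(a), _lengths(b)
    if len(xa) < 2 or len(xb) < 2:
        raise InsufficientDataError("variance ratio test needs n >= 2 in both groups")
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va <= 0 or vb <= 0:
        raise DegenerateDataError("zero variance in one group; F test undefined")
    F = va / vb
    df1, df2 = len(xa) - 1, len(xb) - 1
    p = 2.0 * min(stats.f.cdf(F, df1, df2), stats.f.sf(F, df1, df2))
    return float(F), df1, df2, float(min(p, 1.0))


def bartlett_test(groups: Mapping[str, Iterable]) -> VarianceComparison:
    """Bartlett's K² homogeneity-of-variance test across named groups,
    plus pairwise variance-ratio F tests for every unordered pair."""
    if len(groups) < 2:
        raise ConfigError("Bartlett test needs >= 2 groups")
    arrays = {k: _lengths(v) for k, v in groups.items()}
    for k, arr in arrays.items():
        if len(arr) < 2:
            raise InsufficientDataError(f"group {k!r} has fewer than 2 observations")
        if arr.var(ddof=1) <= 0:
            raise DegenerateDataError(f"group {k!r} has zero variance")
    k2, p = stats.bartlett(*arrays.values())
    pairwise = {}
    for a, b in itertools.combinations(arrays, 2):
        F, df1, df2, pf = variance_ratio_test(arrays[a], arrays[b])
        pairwise[(a, b)] = {"F": F, "df1": df1, "df2": df2, "p": pf}
    return VarianceComparison(
        bartlett_k2=float(k2), bartlett_df=len(arrays) - 1, bartlett_p=float(p),
        pairwise=pairwise,
    )


def _parent_col(parent_tactic: str) -> str:
    return "dam_id" if parent_tactic == "female" else "sire_id"


def parent_offspring_regression(
    p: Union[Pedigree, pd.DataFrame],
    parent_tactic: str,
    offspring_tactic: str,
) -> tuple[float, float, int]:
    """Single parent–offspring regression slope for one grid cell.

    For every parent of ``parent_tactic`` (dams when female, sires
    otherwise) the response is the *mean* length of that parent's offspring
    of ``offspring_tactic`` — one unweighted point per parent regardless of
    family size — regressed on the parent's own length.  Returns
    ``(b_op, se_slope, n_families)``.
    """
    if parent_tactic not in TACTICS or offspring_tactic not in TACTICS:
        raise ConfigError(f"tactics must be in {TACTICS}")
    df = p.frame if isinstance(p, Pedigree) else p
    parents = df[df["generation"].eq("parent") & df["tactic"].eq(parent_tactic)]
    off = df[df["generation"].eq("offspring") & df["tactic"].eq(offspring_tactic)]
    link = _parent_col(parent_tactic)
    off = off[off[link].notna() & off[link].isin(set(parents["id"]))]
    cell = f"{offspring_tactic}~{parent_tactic}"
    if off.empty:
        raise InsufficientDataError(f"no matched families in cell {cell}")
    mean_off = off.groupby(link, observed=True)["length_mm"].mean()
    x = parents.set_index("id").loc[mean_off.index, "length_mm"].astype(float).to_numpy()
    y = mean_off.astype(float).to_numpy()
    n = len(y)
    if n < 3:
        raise InsufficientDataError(f"cell {cell}: needs >= 3 families, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"cell {cell}: parent lengths are constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.params[1]), float(res.bse[1]), n


def heritability_from_slope(
    b_op: float,
    se_slope: float,
    sigma_p: float,
    sigma_o: float,
    corrected: bool,
    n_families: int = 0,
    parent_tactic: str = "",
    offspring_tactic: str = "",
) -> HeritabilityEstimate:
    """Assemble a :class:`HeritabilityEstimate` from a regression slope.

    ``corrected=False`` gives the classical ``h² = 2·b_op`` with null slope
    0.5; ``corrected=True`` rescales by ``σ_p/σ_o`` and moves the h² = 1
    null slope to ``0.5/(σ_p/σ_o)``.  The 95% CI half-width is
    ``1.96·2·se_slope`` times the same correction.
    """
    if not (sigma_p > 0 and sigma_o > 0):
        raise ConfigError(f"sigma_p and sigma_o must be positive, got {sigma_p}, {sigma_o}")
    corr = (sigma_p / sigma_o) if corrected else 1.0
    h2 = 2.0 * b_op * corr
    ci95 = CI_Z * 2.0 * se_slope * corr
    null_slope = 0.5 / corr
    if n_families > 2 and se_slope > 0:
        t0, p0, F1, p1 = _slope_tests(b_op, se_slope, n_families, null_slope)
    else:
        t0 = p0 = F1 = p1 = float("nan")
    return HeritabilityEstimate(
        parent_tactic=parent_tactic, offspring_tactic=offspring_tactic,
        b_op=b_op, se_slope=se_slope, n_families=n_families,
        sigma_p=sigma_p, sigma_o=sigma_o,
        corrected=corrected, correction=corr, h2=h2, ci95=ci95,
        null_slope_h2_one=null_slope,
        t_zero=t0, p_zero=p0, F_one=F1, p_one=p1,
    )


def _slope_tests(b_op, se_slope, n_families, null_value):
    dfree = n_families - 2
    t0 = b_op / se_slope
    p0 = 2.0 * stats.t.sf(abs(t0), dfree)
    F1 = ((b_op - null_value) / se_slope) ** 2
    p1 = stats.f.sf(F1, 1, dfree)
    return float(t0), float(p0), float(F1), float(p1)


def test_slope(
    b_op: float, se_slope: float, n_families: int, null_value: float
) -> dict:
    """Dual hypothesis tests on a parent–offspring slope.

    Returns the t test of slope = 0 (``t``, ``df``, ``p_zero``) and the F
    test of slope = ``null_value`` (``F``, dfs ``(1, n−2)``, ``p_null``).
    When ``null_value`` is 0 the two tests coincide and ``F = t²``.
    """
    if not se_slope > 0:
        raise DegenerateDataError("se_slope must be positive")
    if n_families <= 2:
        raise InsufficientDataError("slope tests need n_families > 2")
    t0, p0, _, _ = _slope_tests(b_op, se_slope, n_families, 0.0)
    _, _, F1, p1 = _slope_tests(b_op, se_slope, n_families, null_value)
    return {
        "t": t0, "df": n_families - 2, "p_zero": p0,
        "F": F1, "df_F": (1, n_families - 2), "p_null": p1,
        "null_value": null_value,
    }


def heritability_grid(
    p: Union[Pedigree, pd.DataFrame],
    alpha_var: float = 0.05,
) -> dict[tuple, Union[HeritabilityEstimate, str]]:
    """All nine parent-tactic × offspring-tactic heritability estimates.

    σ_p is the sample SD of length over *parent-generation* individuals of
    the parent tactic and σ_o over *offspring-generation* individuals of
    the offspring tactic.  For intertactical cells the Falconer correction
    is applied iff the two-sided variance-ratio F test between those same
    two groups rejects at ``alpha_var``; intratactical (diagonal) cells are
    never corrected.  Cells with insufficient data map to a reason string
    instead of an estimate.
    """
    df = p.frame if isinstance(p, Pedigree) else p
    par = df[df["generation"].eq("parent")]
    off = df[df["generation"].eq("offspring")]
    sig_p = {t: par.loc[par["tactic"].eq(t), "length_mm"].astype(float) for t in TACTICS}
    sig_o = {t: off.loc[off["tactic"].eq(t), "length_mm"].astype(float) for t in TACTICS}

    grid: dict[tuple, Union[HeritabilityEstimate, str]] = {}
    for pt in TACTICS:
        for ot in TACTICS:
            xp, xo = sig_p[pt], sig_o[ot]
            if len(xp) < 2 or len(xo) < 2:
                grid[(pt, ot)] = "no parent or offspring individuals of the required tactic"
                continue
            sp, so = xp.std(ddof=1), xo.std(ddof=1)
            corrected = False
            if pt != ot and sp > 0 and so > 0:
                _, _, _, p_var = variance_ratio_test(xp, xo)
                corrected = p_var < alpha_var
            try:
                b, se, n = parent_offspring_regression(df, pt, ot)
            except (InsufficientDataError, DegenerateDataError) as exc:
                grid[(pt, ot)] = str(exc)
                continue
            grid[(pt, ot)] = heritability_from_slope(
                b, se, float(sp), float(so), corrected,
                n_families=n, parent_tactic=pt, offspring_tactic=ot,
            )
    return grid


def grid_frame(grid: Mapping[tuple, Union[HeritabilityEstimate, str]]) -> pd.DataFrame:
    """Flatten a heritability grid into a tidy table (NA rows keep the reason)."""
    rows = []
    for (pt, ot), est in grid.items():
        if isinstance(est, str):
            rows.append({"parent_tactic": pt, "offspring_tactic": ot, "note": est})
        else:
            d = est.__dict__.copy()
            d["note"] = ""
            rows.append(d)
    cols = ["parent_tactic", "offspring_tactic", "b_op", "se_slope", "n_families",
            "sigma_p", "sigma_o", "corrected", "correction", "h2", "ci95",
            "null_slope_h2_one", "t_zero", "p_zero", "F_one", "p_one", "note"]
    return pd.DataFrame(rows).reindex(columns=cols)


def offspring_interaction_model(p: Union[Pedigree, pd.DataFrame]) -> OffspringInteractionFit:
    """Offspring length on dam length, sire length, offspring tactic and the
    two length × tactic interactions; one row per offspring with both
    parents known.  Per-term F tests use sequential (type-I) sums of
    squares in the equation's term order."""
    df = p.frame if isinstance(p, Pedigree) else p
    off = df[df["generation"].eq("offspring")].copy()
    off = off[off["dam_id"].notna() & off["sire_id"].notna()]
    if off.empty:
        raise InsufficientDataError("no offspring with both parents known")
    lengths = df.set_index("id")["length_mm"].astype(float)
    off["dam_length"] = off["dam_id"].map(lengths)
    off["sire_length"] = off["sire_id"].map(lengths)
    off = off.dropna(subset=["dam_length", "sire_length", "length_mm"])
    if off["tactic"].nunique() < 2:
        raise DegenerateDataError("offspring interaction model needs >= 2 offspring tactics")
    off["length"] = off["length_mm"].astype(float)
    terms = ["dam_length", "sire_length", "C(tactic)",
             "dam_length:C(tactic)", "sire_length:C(tactic)"]
    res = smf.ols("length ~ " + " + ".join(terms), data=off).fit()
    if res.df_resid <= 0 or np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        raise DegenerateDataError("rank-deficient design in the offspring interaction model")
    # sequential (type-I) sums of squares in the equation's own term order,
    # via incremental nested fits (patsy would reorder categorical terms)
    mse = res.ssr / res.df_resid
    rows, prev = [], smf.ols("length ~ 1", data=off).fit()
    for i, term in enumerate(terms):
        cur = smf.ols("length ~ " + " + ".join(terms[: i + 1]), data=off).fit()
        ss = prev.ssr - cur.ssr
        dfree = prev.df_resid - cur.df_resid
        F = (ss / dfree) / mse if dfree > 0 else np.nan
        rows.append({"term": term, "sum_sq": ss, "df": dfree, "F": F,
                     "p": float(stats.f.sf(F, dfree, res.df_resid)) if dfree > 0 else np.nan})
        prev = cur
    rows.append({"term": "Residual", "sum_sq": res.ssr, "df": res.df_resid,
                 "F": np.nan, "p": np.nan})
    anova = pd.DataFrame(rows).set_index("term")
    return OffspringInteractionFit(
        params=res.params,
        anova=anova,
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )
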