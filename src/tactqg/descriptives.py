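"""Descriptive comparisons among tactics: length ANOVA with Tukey HSD and
count GLMs (Poisson / negative binomial) of reproductive success."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ConfigError, DegenerateDataError
from .pedigree import Pedigree, TACTICS

__all__ = ["AnovaResult", "CountGlmResult", "length_anova", "rs_count_glm", "tactic_summary"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame   # index = tactic; mean, se, n, min, max
    tukey: pd.DataFrame         # columns: group1, group2, diff, p_adj


@dataclass(frozen=True)
class CountGlmResult:
    family: str                 # "poisson" | "negative_binomial"
    alpha: Optional[float]      # NB dispersion (var = mu + alpha*mu^2); None for Poisson
    chi_sq: float               # LR statistic for the tactic term
    df: int
    p: float
    llf_full: float
    llf_null: float
    converged: bool
    group_means: pd.Series


def _frame(data: Union[Pedigree, pd.DataFrame]) -> pd.DataFrame:
    return data.frame if isinstance(data, Pedigree) else data


def tactic_summary(p: Union[Pedigree, pd.DataFrame]) -> pd.DataFrame:
    """Per-tactic length and reproductive-success descriptives (mean, SE, range)."""
    df = _frame(p)
    rows = []
    for t in [t for t in TACTICS if t in set(df["tactic"])]:
        g = df[df["tactic"].eq(t)]
        length = g["length_mm"].astype(float)
        rs = g["rs"].astype(float)
        rows.append({
            "tactic": t, "n": len(g),
            "length_mean": length.mean(), "length_se": length.std(ddof=1) / np.sqrt(len(g)),
            "length_min": length.min(), "length_max": length.max(),
            "rs_mean": rs.mean(), "rs_se": rs.std(ddof=1) / np.sqrt(len(g)),
            "rs_min": rs.min(), "rs_max": rs.max(),
        })
    return pd.DataFrame(rows).set_index("tactic")


def length_anova(p: Union[Pedigree, pd.DataFrame]) -> AnovaResult:
    """One-way fixed-effects ANOVA of length among tactics with Tukey HSD
    (Tukey–Kramer for the unbalanced case) on all pairs."""
    df = _frame(p)
    groups = {t: df.loc[df["tactic"].eq(t), "length_mm"].astype(float).to_numpy()
              for t in TACTICS if (df["tactic"] == t).any()}
    if len(groups) < 2:
        raise DegenerateDataError("length ANOVA needs >= 2 tactics")
    for t, arr in groups.items():
        if len(arr) < 2:
            raise DegenerateDataError(f"tactic {t!r} has fewer than 2 individuals")
    F, pval = stats.f_oneway(*groups.values())
    n_tot = sum(len(a) for a in groups.values())
    k = len(groups)
    stats_rows = {
        t: {"mean": a.mean(), "se": a.std(ddof=1) / np.sqrt(len(a)), "n": len(a),
            "min": a.min(), "max": a.max()}
        for t, a in groups.items()
    }
    endog = np.concatenate(list(groups.values()))
    labels = np.concatenate([[t] * len(a) for t, a in groups.items()])
    if np.ptp(endog) == 0:
        # identical data in every group: F is exactly 0, Tukey is vacuous
        tukey_df = pd.DataFrame(
            [{"group1": a, "group2": b, "diff": 0.0, "p_adj": 1.0}
             for i, a in enumerate(groups) for b in list(groups)[i + 1:]]
        )
        return AnovaResult(0.0, k - 1, n_tot - k, 1.0,
                           pd.DataFrame(stats_rows).T, tukey_df)
    tk = pairwise_tukeyhsd(endog, labels)
    pairs = _tukey_pairs(tk)
    tukey_df = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "diff": tk.meandiffs,
        "p_adj": tk.pvalues,
    })
    return AnovaResult(
        F=float(F), df_between=k - 1, df_within=n_tot - k, p=float(pval),
        group_stats=pd.DataFrame(stats_rows).T, tukey=tukey_df,
    )


def _tukey_pairs(tk) -> list[tuple]:
    su = list(tk.groupsunique)
    return [(su[i], su[j]) for i in range(len(su)) for j in range(i + 1, len(su))]


def rs_count_glm(p: Union[Pedigree, pd.DataFrame], family: str = "negative_binomial") -> CountGlmResult:
    """Count GLM of reproductive success on tactic with a likelihood-ratio
    test of the tactic term (df = number of tactics − 1).

    The negative binomial uses the NB2 mean/dispersion parameterization
    with a log link; the dispersion ``alpha`` is estimated by maximum
    likelihood jointly with the mean model (in both the full and the
    intercept-only fit, as is standard for LR tests of mean structure).
    """
    df = _frame(p).copy()
    rs = pd.to_numeric(df["rs"])
    if (rs < 0).any() or (rs != np.floor(rs)).any():
        raise ConfigError("rs must be nonnegative integers")
    df["rs"] = rs.astype(float)
    k = df["tactic"].nunique()
    if k < 2:
        raise DegenerateDataError("count GLM of tactic needs >= 2 tactics")

    if family == "poisson":
        full = smf.glm("rs ~ C(tactic)", df, family=sm.families.Poisson()).fit()
        null = smf.glm("rs ~ 1", df, family=sm.families.Poisson()).fit()
        alpha = None
        converged = bool(full.converged and null.converged)
    elif family == "negative_binomial":
        full = smf.negativebinomial("rs ~ C(tactic)", df).fit(disp=0, maxiter=500, method="bfgs")
        null = smf.negativebinomial("rs ~ 1", df).fit(disp=0, maxiter=500, method="bfgs")
        alpha = float(full.params["alpha"])
        converged = bool(full.mle_retvals.get("converged", False)
                         and null.mle_retvals.get("converged", False))
    else:
        raise ConfigError(f"family must be 'poisson' or 'negative_binomial', got {family!r}")

    chi = max(0.0, 2.0 * (full.llf - null.llf))
    return CountGlmResult(
        family=family, alpha=alpha,
        chi_sq=float(chi), df=k - 1, p=float(stats.chi2.sf(chi, k - 1)),
        llf_full=float(full.llf), llf_null=float(null.llf),
        converged=converged,
        group_means=df.groupby("tactic", observed=True)["rs"].mean(),
    )
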