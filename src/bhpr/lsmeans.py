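"""Categorical-age mixed model baseline: LS-means, Tukey-adjusted per-age
group contrasts, and the two divergence-age read-outs.

This is the traditional comparator: a linear mixed model with age treated as
an unordered factor crossed with group and a random subject intercept.  The
model-implied cell means (LS-means) are compared between groups at every age
level; the age at divergence is then read off either as the earliest age
with an adjusted p-value below alpha, or as the midway point between the
consecutive ages that best separate non-significant from significant
contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import studentized_range, t as t_dist
from statsmodels.regression.mixed_linear_model import MixedLM

from .data import AGE, GROUP, LongitudinalDataset

__all__ = [
    "LsmeansResult", "fit_categorical_mixed", "tukey_pairwise",
    "earliest_significant_age", "midway_divergence_age",
]


@dataclass(frozen=True)
class LsmeansResult:
    """Estimated marginal means per (age level, group) and per-age group
    contrasts (group 1 minus group 0), with unadjusted and, after
    :func:`tukey_pairwise`, Tukey-adjusted p-values."""

    means: pd.DataFrame       # age, group, lsmean, se
    contrasts: pd.DataFrame   # age, estimate, se, t, df, p_unadj [, p_adj]
    excluded_ages: tuple = ()

    @property
    def ages(self) -> np.ndarray:
        return self.contrasts[AGE].to_numpy(float)

    def adjusted_p(self) -> np.ndarray:
        if "p_adj" not in self.contrasts:
            raise ValueError("run tukey_pairwise first")
        return self.contrasts["p_adj"].to_numpy(float)


def fit_categorical_mixed(ds: LongitudinalDataset,
                          age_levels: np.ndarray | None = None,
                          covariates: tuple[str, ...] = (),
                          reml: bool = True,
                          optimizer: str = "lbfgs") -> LsmeansResult:
    """Fit ``response ~ C(age) * group + (1 | subject)`` via cell-means coding.

    Ages are treated as discrete levels (the exact visit ages by default; for
    ragged real data pass explicit ``age_levels`` bin representatives after
    binning upstream).  With cell-means coding each fixed coefficient *is*
    the LS-mean of its (age, group) cell (covariates, if any, are centered so
    LS-means are evaluated at covariate means).  Age levels observed in only
    one group are excluded from the contrast table with a warning.
    """
    if not ds.has_group:
        raise ValueError("dataset has no group column")
    df = ds.frame
    age = df[AGE].to_numpy(float)
    if age_levels is None:
        age_levels = np.unique(age)
    age_levels = np.sort(np.asarray(age_levels, float))
    lvl_idx = np.searchsorted(age_levels, age)
    lvl_idx = np.clip(lvl_idx, 0, len(age_levels) - 1)
    grp = df[GROUP].to_numpy(int)
    y = ds.response

    cells = []
    col_of = {}
    for a_i in range(len(age_levels)):
        for g in (0, 1):
            n_cell = int(np.sum((lvl_idx == a_i) & (grp == g)))
            if n_cell:
                col_of[(a_i, g)] = len(cells)
                cells.append((a_i, g))
    X = np.zeros((len(y), len(cells) + len(covariates)))
    for j, (a_i, g) in enumerate(cells):
        X[:, j] = (lvl_idx == a_i) & (grp == g)
    for q, cov in enumerate(covariates):
        c = df[cov].to_numpy(float)
        X[:, len(cells) + q] = c - np.nanmean(c)

    # some optimizers terminate "successfully" at degenerate points with
    # absurd standard errors; treat those like failures and fall back
    se_cap = 1e3 * max(float(np.std(y)), 1e-8)
    tried, fit = [], None
    for meth in dict.fromkeys([optimizer, "bfgs", "cg", "powell"]):
        model = MixedLM(y, X, groups=df["subject"].to_numpy())
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cand = model.fit(reml=reml, method=meth)
            bse = np.asarray(cand.bse_fe)
            if np.isfinite(bse).all() and bse.max() < se_cap:
                fit = cand
                break
        except np.linalg.LinAlgError:
            pass
        tried.append(meth)
    if fit is None:
        raise np.linalg.LinAlgError(
            f"mixed-model fit failed or degenerate with optimizers {tried}")
    beta = fit.fe_params
    V = fit.cov_params()[: len(cells) + len(covariates),
                         : len(cells) + len(covariates)]
    dof = max(len(y) - X.shape[1], 1)

    mrows, crows, excluded = [], [], []
    for a_i, a in enumerate(age_levels):
        have = [g for g in (0, 1) if (a_i, g) in col_of]
        for g in have:
            j = col_of[(a_i, g)]
            mrows.append({AGE: a, GROUP: g, "lsmean": beta[j],
                          "se": np.sqrt(V[j, j])})
        if len(have) < 2:
            if have:
                excluded.append(a)
            continue
        j0, j1 = col_of[(a_i, 0)], col_of[(a_i, 1)]
        est = beta[j1] - beta[j0]
        se = float(np.sqrt(V[j0, j0] + V[j1, j1] - 2 * V[j0, j1]))
        tval = est / se
        crows.append({AGE: a, "estimate": est, "se": se, "t": tval,
                      "df": dof, "p_unadj": 2 * t_dist.sf(abs(tval), dof)})
    if excluded:
        warnings.warn(f"age levels {excluded} present in only one group; "
                      "excluded from contrasts", UserWarning)
    return LsmeansResult(means=pd.DataFrame(mrows),
                         contrasts=pd.DataFrame(crows),
                         excluded_ages=tuple(excluded))


def _range_param(n_contrasts: int) -> int:
    """Number of means k whose pairwise comparisons match the family size:
    smallest k with k(k-1)/2 >= m.  m=1 gives k=2, i.e. no adjustment."""
    k = 2
    while k * (k - 1) // 2 < n_contrasts:
        k += 1
    return k


def tukey_pairwise(lsres: LsmeansResult) -> LsmeansResult:
    """Studentized-range (Tukey) adjusted p-values for the per-age contrasts.

    The family is the set of per-age group contrasts (not all cell pairs);
    its size m is mapped to the range parameter k with k(k-1)/2 >= m so the
    multiplicity of Tukey's all-pairs procedure matches the family size.
    A single contrast is returned unadjusted (k = 2 reduces exactly to the
    two-sided t test).
    """
    ctr = lsres.contrasts.copy()
    if not len(ctr):
        return replace(lsres, contrasts=ctr)
    k = _range_param(len(ctr))
    q = np.sqrt(2.0) * np.abs(ctr["t"].to_numpy())
    p_adj = studentized_range.sf(q, k, ctr["df"].to_numpy())
    ctr["p_adj"] = np.minimum(1.0, np.maximum(p_adj, 0.0))
    return replace(lsres, contrasts=ctr)


def earliest_significant_age(lsres: LsmeansResult,
                             alpha: float = 0.05) -> float | None:
    """Smallest age level whose adjusted group contrast has p < alpha
    (taken literally even if later ages are non-significant)."""
    p = lsres.adjusted_p()
    ages = lsres.ages
    sig = p < alpha
    return float(ages[sig][0]) if sig.any() else None


def midway_divergence_age(lsres: LsmeansResult,
                          alpha: float = 0.05) -> float | None:
    """Midpoint between the consecutive age levels that best split
    non-significant contrasts (before) from significant ones (after).

    Every cut between consecutive age levels is scored by its
    misclassifications (significant ages before the cut plus non-significant
    ages after it); the earliest minimal-misclassification cut wins.  All
    levels significant -> the first age level; none significant -> ``None``.
    """
    p = lsres.adjusted_p()
    ages = lsres.ages
    sig = p < alpha
    if not sig.any():
        return None
    if sig.all():
        return float(ages[0])
    m = len(ages)
    cum_sig = np.concatenate([[0], np.cumsum(sig)])
    best_c, best_cost = None, None
    for c in range(1, m):
        cost = cum_sig[c] + ((m - c) - (cum_sig[m] - cum_sig[c]))
        if best_cost is None or cost < best_cost:
            best_c, best_cost = c, cost
    return float(0.5 * (ages[best_c - 1] + ages[best_c]))
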