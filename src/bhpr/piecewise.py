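"""Broken-stick mean function, likelihood, and profile-likelihood change point.

The mean is continuous at the change point by construction: the second
segment adds ``b2 * (age - cp)_+`` to the extended first-phase line, so the
slope is ``b1`` below the change point and ``b1 + b2`` above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LongitudinalDataset
from .model import FixedEffects, ModelSpec

__all__ = ["PiecewiseParams", "piecewise_mean", "loglik", "profile_loglik_cp",
           "ProfileCPResult"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class PiecewiseParams:
    """One broken-stick curve: level at a_ref, pre-CP slope, slope change, CP."""

    b0: float
    b1: float
    b2: float
    cp: float

    def __post_init__(self):
        if not np.isfinite(self.cp):
            raise ValueError("change point must be finite")


def piecewise_mean(params: PiecewiseParams, age, a_ref: float = 0.0):
    """Evaluate ``b0 + b1*(age - a_ref) + b2*(age - cp)_+`` (cp on raw age)."""
    age = np.asarray(age, float)
    return (params.b0
            + params.b1 * (age - a_ref)
            + params.b2 * np.maximum(age - params.cp, 0.0))


def _linear_predictor(ds: LongitudinalDataset, fixed: FixedEffects,
                      spec: ModelSpec, random: dict | None) -> np.ndarray:
    """Row-level mean given fixed effects, optional random effects, TVCs."""
    age = ds.ages
    a_ref = spec.age_center if spec.age_center is not None else float(age.mean())
    idx = ds.subject_index()
    grp_s = ds.group_by_subject()
    S = ds.n_subjects

    def shift(name):
        return fixed.beta_grp.get(name, 0.0)

    b0 = np.full(S, fixed.beta00) + shift("b0") * grp_s
    b1 = np.full(S, fixed.beta10) + shift("b1") * grp_s
    b2 = np.full(S, fixed.beta20) + shift("b2") * grp_s
    cp = np.full(S, fixed.cp) + shift("cp") * grp_s
    for param, vec in (("b0", b0), ("b1", b1), ("b2", b2), ("cp", cp)):
        for tic in spec.tic_terms.get(param, ()):  # level-2 TIC effects
            coef = fixed.beta_tic.get((param, tic), 0.0)
            vec += coef * ds.tics_by_subject([tic])[:, 0]
    if random:
        b0 = b0 + random.get("intercept", 0.0)
        b1 = b1 + random.get("slope_pre", 0.0)
        b2 = b2 + random.get("slope_change", 0.0)
        cp = cp + random.get("cp", 0.0)

    mu = b0[idx] + b1[idx] * (age - a_ref)
    if not spec.linear_only:
        mu = mu + b2[idx] * np.maximum(age - cp[idx], 0.0)
    if spec.tvc_terms:
        x, mask = ds.tvc_matrix()
        for j, name in enumerate(ds.tvc_cols):
            if name in spec.tvc_terms:
                col = x[:, j]
                if mask[:, j].any():
                    raise ValueError(
                        f"TVC {name!r} has missing values; impute before loglik")
                mu = mu + fixed.beta_tvc.get(name, 0.0) * col
    return mu


def loglik(ds: LongitudinalDataset, fixed: FixedEffects, sigma: float,
           spec: ModelSpec | None = None, random: dict | None = None) -> float:
    """Gaussian log-likelihood of the dataset at the given trajectory state.

    ``random`` may hold per-subject arrays for ``intercept``, ``slope_pre``,
    ``slope_change`` and ``cp`` deviations; missing TVC values must already be
    imputed.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    spec = spec or ModelSpec(random_effects=(), divergence_type="none")
    mu = _linear_predictor(ds, fixed, spec, random)
    r = ds.response - mu
    n = len(r)
    return float(-0.5 * n * (_LOG2PI + 2.0 * np.log(sigma)) - 0.5 * (r @ r) / sigma ** 2)


@dataclass(frozen=True)
class ProfileCPResult:
    """Profile log-likelihood over a change-point grid."""

    cp_hat: float
    grid: np.ndarray
    loglik: np.ndarray
    flat: bool  #: True when the profile is (numerically) constant -> no break

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"cp": self.grid, "loglik": self.loglik})


def profile_loglik_cp(ds: LongitudinalDataset,
                      cp_grid: np.ndarray | None = None,
                      rows: np.ndarray | None = None) -> ProfileCPResult:
    """Population change point by profiling the fixed-effects log-likelihood.

    For each candidate cp the two-slope fixed-effects model (random effects
    omitted) is fit by least squares and the Gaussian profile log-likelihood
    recorded; the argmax is returned (smallest cp on ties).  The default grid
    steps by 0.5 years over ``[age_min + 2, age_max - 2]`` so both segments
    remain estimable.
    """
    age = ds.ages
    y = ds.response
    if rows is not None:
        age, y = age[rows], y[rows]
    lo, hi = float(age.min()), float(age.max())
    if cp_grid is None:
        cp_grid = np.arange(lo + 2.0, hi - 2.0 + 1e-9, 0.5)
        if len(cp_grid) == 0:
            cp_grid = np.array([0.5 * (lo + hi)])
    cp_grid = np.asarray(cp_grid, float)
    if cp_grid.min() < lo or cp_grid.max() > hi:
        raise ValueError(f"cp grid outside observed age range [{lo}, {hi}]")
    for cp in (cp_grid.min(), cp_grid.max()):
        if (age < cp).sum() < 2 or (age > cp).sum() < 2:
            raise ValueError(f"fewer than 2 observations on one side of cp={cp}")

    agec = age - age.mean()
    n = len(y)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    # numerically-zero residual floor keeps the curve finite and shift-stable
    floor = max(1e-15 * ss_total / n, 1e-300)
    X0 = np.column_stack([np.ones(n), agec])
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss_nobreak = float(np.sum((y - X0 @ beta0) ** 2))
    rsss = np.empty(len(cp_grid))
    lls = np.empty(len(cp_grid))
    for k, cp in enumerate(cp_grid):
        X = np.column_stack([np.ones(n), agec, np.maximum(age - cp, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rsss[k] = float(np.sum((y - X @ beta) ** 2))
        lls[k] = -0.5 * n * (_LOG2PI + np.log(max(rsss[k] / n, floor)) + 1.0)
    # flat = no grid point improves on the straight line beyond float noise
    flat = bool(rss_nobreak - rsss.min() <= 1e-9 * max(ss_total, 1e-12))
    cp_hat = float(cp_grid[0]) if flat else float(cp_grid[np.argmin(rsss)])
    return ProfileCPResult(cp_hat=cp_hat, grid=cp_grid, loglik=lls, flat=flat)
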