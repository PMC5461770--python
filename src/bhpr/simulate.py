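"""Generative engine for piecewise longitudinal data under divergence
mechanisms with an accelerated longitudinal design.

The default scenario reproduces the published simulation conditions for a
Type II divergence (group 2 reaches the change point later): generating
trajectory values b0 = 26.5 kg/m2 (at the reference age), pre-CP slope
0.67 kg/m2/yr, slope change -0.49 kg/m2/yr, CP = 16.02 yr, group CP shift
+12.37 yr, a participant-level random-intercept variance of 2.77 and a
residual variance of 2.47.  The design emulates a six-cohort accelerated
longitudinal study: entry ages are drawn uniformly from {3, 6, 9, 12, 15,
18} years and each participant is measured 3, 6, 9, 21, 27 and 31 years
after entry (six measures per participant, observed ages spanning 6-49).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import AGE, COHORT, GROUP, RESPONSE, SUBJECT, LongitudinalDataset
from .model import FixedEffects

__all__ = ["TVCSimModel", "SimScenario", "simulate_dataset",
           "make_default_paper_scenario", "simulate_cohort_shifts"]

_PARAM_NAMES = ("b0", "b1", "b2", "cp")


@dataclass(frozen=True)
class TVCSimModel:
    """Gaussian visit-level covariate entering the response directly,
    with MAR missingness independent of the covariate value."""

    name: str = "tvc"
    mean: float = 0.0
    sd: float = 1.0
    beta: float = 1.0          # effect on the response per unit covariate
    missing_rate: float = 0.17


@dataclass(frozen=True)
class SimScenario:
    """Generating truth + design for one simulation condition."""

    n_group1: int = 100
    n_group2: int = 100
    truth: FixedEffects = field(default_factory=lambda: FixedEffects(
        beta00=26.5, beta10=0.67, beta20=-0.49, cp=16.02,
        beta_grp={"cp": 12.37}))
    var_u0: float = 2.77       # participant-level random-intercept variance
    var_u1: float = 0.0
    var_u2: float = 0.0
    var_cp: float = 0.0
    re_cov: np.ndarray | None = None   # optional full 4x4 covariance override
    var_e: float = 2.47        # observation-level residual variance
    baseline_ages: tuple = (3, 6, 9, 12, 15, 18)
    offsets: tuple = (3, 6, 9, 21, 27, 31)
    a_ref: float = 25.0
    tvc: TVCSimModel | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.n_group1 <= 0 or self.n_group2 <= 0:
            raise ValueError("group sizes must be > 0")
        for v in (self.var_u0, self.var_u1, self.var_u2, self.var_cp,
                  self.var_e):
            if v < 0:
                raise ValueError("variances must be >= 0")
        if not all(b < a for b, a in zip(self.offsets, self.offsets[1:])):
            raise ValueError("follow-up offsets must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2

    def re_covariance(self) -> np.ndarray:
        if self.re_cov is not None:
            C = np.asarray(self.re_cov, float)
            if C.shape != (4, 4) or not np.allclose(C, C.T):
                raise ValueError("re_cov must be a symmetric 4x4 matrix")
            return C
        return np.diag([self.var_u0, self.var_u1, self.var_u2, self.var_cp])


def make_default_paper_scenario(sizes: tuple[int, int] = (100, 100),
                                seed: int | None = None) -> SimScenario:
    """The published Type II simulation condition at one of the three sample
    sizes (100/100, 50/100, 30/100) or any custom pair."""
    return SimScenario(n_group1=sizes[0], n_group2=sizes[1], seed=seed)


def _draw_random_effects(scn: SimScenario, rng, n: int) -> np.ndarray:
    C = scn.re_covariance()
    if not C.any():
        return np.zeros((n, 4))
    # eigen-based square root tolerates semidefinite (zero-variance) blocks
    w, Q = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    A = Q * np.sqrt(w)
    return rng.standard_normal((n, 4)) @ A.T


def _simulate(scn: SimScenario, rng, cohort_effects: dict | None):
    S = scn.n_subjects
    grp = np.concatenate([np.zeros(scn.n_group1), np.ones(scn.n_group2)])
    baseline = rng.choice(np.asarray(scn.baseline_ages, float), size=S)
    V = _draw_random_effects(scn, rng, S)
    tr = scn.truth

    def shift(name):
        return tr.beta_grp.get(name, 0.0)

    b0 = tr.beta00 + shift("b0") * grp + V[:, 0]
    b1 = tr.beta10 + shift("b1") * grp + V[:, 1]
    b2 = tr.beta20 + shift("b2") * grp + V[:, 2]
    cp = tr.cp + shift("cp") * grp + V[:, 3]

    cohort = None
    if cohort_effects is not None:
        levels = sorted(scn.baseline_ages)
        cohort = np.array([f"b{int(b)}" for b in baseline])
        for label, shifts in cohort_effects.items():
            for pname in shifts:
                if pname not in _PARAM_NAMES:
                    raise ValueError(f"unknown trajectory parameter {pname!r}")
            mask = cohort == label
            b0[mask] += shifts.get("b0", 0.0)
            b1[mask] += shifts.get("b1", 0.0)
            b2[mask] += shifts.get("b2", 0.0)
            cp[mask] += shifts.get("cp", 0.0)
        del levels

    offsets = np.asarray(scn.offsets, float)
    ages = baseline[:, None] + offsets[None, :]          # (S, n_visits)
    lo, hi = ages.min(), ages.max()
    if ((cp < lo) | (cp > hi)).any():
        warnings.warn("some subject change points fall outside the design "
                      "age span; they are unidentifiable from these visits",
                      UserWarning)
    mu = (b0[:, None] + b1[:, None] * (ages - scn.a_ref)
          + b2[:, None] * np.maximum(ages - cp[:, None], 0.0))
    y = mu + np.sqrt(scn.var_e) * rng.standard_normal(ages.shape)

    n_vis = len(offsets)
    frame = pd.DataFrame({
        SUBJECT: np.repeat([f"s{i:05d}" for i in range(S)], n_vis),
        AGE: ages.ravel(),
        RESPONSE: y.ravel(),
        GROUP: np.repeat(grp.astype(int), n_vis),
    })
    tvcs = ()
    if scn.tvc is not None:
        t = scn.tvc
        x = rng.normal(t.mean, t.sd, size=S * n_vis)
        frame[RESPONSE] += t.beta * x
        miss = rng.random(S * n_vis) < t.missing_rate   # MAR: independent of x
        x_obs = x.copy()
        x_obs[miss] = np.nan
        frame[t.name] = x_obs
        tvcs = (t.name,)
    if cohort is not None:
        frame[COHORT] = np.repeat(cohort, n_vis)

    ds = LongitudinalDataset(frame=frame, has_group=True,
                             has_cohort=cohort is not None, tvc_cols=tvcs)
    truth = {
        "b0": tr.beta00, "b1": tr.beta10, "b2": tr.beta20, "cp": tr.cp,
        "beta_grp": dict(tr.beta_grp), "var_u0": scn.var_u0,
        "var_u1": scn.var_u1, "var_u2": scn.var_u2, "var_cp": scn.var_cp,
        "var_e": scn.var_e, "a_ref": scn.a_ref,
        "tvc_beta": (scn.tvc.beta if scn.tvc else None),
    }
    return ds, truth


def simulate_dataset(scenario: SimScenario, seed: int | None = None):
    """Draw one dataset from the scenario; returns ``(dataset, truth)``.

    Per subject: an entry age is drawn from the design distribution, visits
    occur at the follow-up offsets, random effects are drawn from the
    requested covariance, group-2 subjects get the specified trajectory
    shifts, and responses are the broken-stick mean plus residual noise.
    The MAR mask (if a TVC model is present) is independent of the masked
    values.  Identical scenario + seed give identical datasets.
    """
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    return _simulate(scenario, rng, cohort_effects=None)


def simulate_cohort_shifts(scenario: SimScenario, cohort_effects: dict,
                           seed: int | None = None):
    """Like :func:`simulate_dataset` but with birth-cohort labels (one per
    entry age, labelled ``b<age>``) and per-cohort trajectory-parameter
    shifts applied before response generation.  With all shifts zero the
    result equals :func:`simulate_dataset` at the same seed, plus the cohort
    column."""
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    return _simulate(scenario, rng, cohort_effects=cohort_effects)
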