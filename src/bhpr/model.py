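"""Model specification, fixed-effect containers, and prior hyperparameters.

The mean trajectory is the continuous broken-stick curve

    mu_ij = b0_i + b1_i (age_ij - a_ref) + b2_i (age_ij - CP_i)_+  [+ TVC terms]

with subject-level parameters (b0, b1, b2, CP) decomposed at level 2 into a
population value, optional group shifts (the divergence mechanism), optional
TIC effects, and random effects.  Which of the four group shifts are free is
the *divergence type*; the candidate suite A..H sequentially frees them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec", "FixedEffects", "PriorSet",
    "DIVERGENCE_FREE", "MODEL_SUITE", "MODEL_LABELS",
]

#: divergence type -> set of free group-shift parameters
DIVERGENCE_FREE = {
    "none": frozenset(),
    "intercept_only": frozenset({"b0"}),
    "childhood_slope": frozenset({"b1"}),
    "adult_slope": frozenset({"b2"}),                      # Type I
    "change_point": frozenset({"cp"}),                     # Type II
    "cp_and_adult_slope": frozenset({"cp", "b2"}),         # Type III
    "cp_childhood_adult_slopes": frozenset({"cp", "b1", "b2"}),
    "cp_and_intercept": frozenset({"cp", "b0"}),
    "all_four": frozenset({"b0", "b1", "b2", "cp"}),
}

#: candidate-model letters -> divergence type
MODEL_SUITE = {
    "A": "none",
    "B": "intercept_only",
    "C": "childhood_slope",
    "D": "adult_slope",
    "E": "change_point",
    "F": "cp_and_adult_slope",
    "G": "cp_and_intercept",
    "H": "all_four",
}

MODEL_LABELS = {
    "A": "Unconditional",
    "B": "Group (intercept b0)",
    "C": "Group (childhood slope b1)",
    "D": "Group (adulthood slope b2)",
    "E": "Group (change point CP)",
    "F": "Group (CP + b2)",
    "G": "Group (CP + b0)",
    "H": "Group (all 4 parameters)",
}

_RE_NAMES = ("intercept", "slope_pre", "slope_change", "cp")
_COV_STRUCTURES = ("full_unstructured", "block_b1b2", "independent")


@dataclass(frozen=True)
class ModelSpec:
    """Which effects are free, which random effects are included, and how.

    Parameters
    ----------
    divergence_type
        One of :data:`DIVERGENCE_FREE`; determines which of the group shifts
        (beta0_grp, beta1_grp, beta2_grp, cp_grp) are free vs pinned to 0.
    cov_structure
        Random-effect covariance: fully unstructured, block-diagonal with a
        free correlation only between the two slope effects, or mutually
        independent components.
    random_effects
        Subset of ``("intercept", "slope_pre", "slope_change", "cp")``.
    tic_terms
        Mapping trajectory parameter ("b0","b1","b2","cp") -> TIC column names
        acting on it at level 2.
    tvc_terms
        TVC column names entering the level-1 mean directly.
    age_center
        Reference age a_ref (years).  ``None`` = grand mean of observed ages.
        The change point is always kept on the raw-age scale.
    linear_only
        Drop the change point entirely (single straight line); used for
        stripped-model checks, not part of the candidate suite.
    """

    divergence_type: str = "none"
    cov_structure: str = "block_b1b2"
    random_effects: tuple[str, ...] = _RE_NAMES
    tic_terms: dict = field(default_factory=dict)
    tvc_terms: tuple[str, ...] = ()
    age_center: float | None = None
    linear_only: bool = False

    def __post_init__(self):
        if self.divergence_type not in DIVERGENCE_FREE:
            raise ValueError(f"unknown divergence type {self.divergence_type!r}")
        if self.cov_structure not in _COV_STRUCTURES:
            raise ValueError(f"unknown covariance structure {self.cov_structure!r}")
        for r in self.random_effects:
            if r not in _RE_NAMES:
                raise ValueError(f"unknown random effect {r!r}")
        for p in self.tic_terms:
            if p not in ("b0", "b1", "b2", "cp"):
                raise ValueError(f"TIC terms attached to unknown parameter {p!r}")

    @property
    def free_group_params(self) -> frozenset[str]:
        free = DIVERGENCE_FREE[self.divergence_type]
        if self.linear_only:
            free = free - {"b2", "cp"}
        return free

    def with_divergence(self, divergence_type: str) -> "ModelSpec":
        return replace(self, divergence_type=divergence_type)


@dataclass
class FixedEffects:
    """Population-average trajectory parameters.

    ``beta20`` is the *change* in slope after the change point; the
    adult-phase slope is ``beta10 + beta20``.  ``cp`` is on the raw-age
    scale regardless of age centering.
    """

    beta00: float
    beta10: float
    beta20: float = 0.0
    cp: float = np.nan
    beta_grp: dict = field(default_factory=dict)   # keys among b0,b1,b2,cp
    beta_tic: dict = field(default_factory=dict)   # (param, tic name) -> coef
    beta_tvc: dict = field(default_factory=dict)   # tvc name -> coef

    @property
    def adult_slope(self) -> float:
        return self.beta10 + self.beta20


@dataclass(frozen=True)
class PriorSet:
    """Hyperparameters for all priors in the hierarchical model.

    Fixed effects get independent normal priors; the default variance 1e4 is
    vague on the response scale so the likelihood dominates.  Variance
    components get Inverse-Gamma(var_a, var_b) priors when independent and an
    InvWishart(iw_scale * I, iw_df) prior on unstructured blocks.  The change
    point mean prior can be anchored at the profile-log-likelihood estimate
    (``cp_mean=None`` requests that at build time).
    """

    beta_mean: float = 0.0
    beta_var: float = 1e4
    cp_mean: float | None = None      # None -> set from profile log-likelihood
    cp_var: float = 1e4
    var_a: float = 0.001              # Inverse-Gamma shape
    var_b: float = 0.001              # Inverse-Gamma scale
    iw_df: float | None = None        # None -> block dimension + 1
    iw_scale: float = 1.0             # scale matrix = iw_scale * I
    tvc_mu_var: float = 1e6           # prior variance of TVC model mean
    tvc_tau_a: float = 0.001          # Gamma prior on TVC precision
    tvc_tau_b: float = 0.001

    def __post_init__(self):
        for name in ("beta_var", "cp_var", "var_a", "var_b", "iw_scale",
                     "tvc_mu_var", "tvc_tau_a", "tvc_tau_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior hyperparameter {name} must be > 0")

    def iw_params(self, dim: int) -> tuple[float, np.ndarray]:
        df = self.iw_df if self.iw_df is not None else dim + 1
        if df < dim + 1:
            raise ValueError("InvWishart degrees of freedom must be >= dim + 1")
        return float(df), self.iw_scale * np.eye(dim)
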