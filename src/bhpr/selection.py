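"""Model comparison: DIC/pD, posterior predictive p-value, group-effect
significance, and the candidate divergence-mechanism suite.

DIC is computed with a level-1 (conditional) focus: the plug-in deviance is
evaluated at posterior means of the fixed effects *and* of the subject random
effects, so pD counts the effective number of parameters of the conditional
likelihood.  A marginal focus is not implemented; the conditional focus is
the natural one for subject-level trajectory comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MODEL_LABELS, MODEL_SUITE, DIVERGENCE_FREE, ModelSpec, PriorSet
from .sampler import (BHPRModel, PosteriorSamples, SamplerConfig, build_model,
                      sample_posterior)

__all__ = [
    "compute_dic", "posterior_predictive_pvalue", "group_effect_significant",
    "fit_divergence_suite", "FitComparison",
]

_GRP_PARAM = {"b0": "beta0_grp", "b1": "beta1_grp", "b2": "beta2_grp",
              "cp": "cp_grp"}


def _plugin_deviance(samples: PosteriorSamples) -> float:
    """Deviance at posterior means of all parameters (random effects at their
    posterior means, missing TVCs at their posterior-mean imputations)."""
    m = samples.model
    theta = np.array([samples.posterior_mean(nm) for nm in m.lin_names])
    v = np.zeros((m.S, m.k_lin))
    for j, rn in enumerate(m.lin_re):
        v[:, j] = samples.re_means[rn]
    vcp = samples.re_means.get("cp", np.zeros(m.S))
    cp = samples.posterior_mean("cp") if m.has_cp else np.nan
    cp_grp = samples.posterior_mean("cp_grp") if m.cp_grp_free else 0.0
    cp_tic = np.array([samples.posterior_mean(nm) for nm in m.cp_tic_names])
    tvc_vals = (samples.tvc_means if samples.tvc_means is not None
                else m.init.get("tvc0", np.empty((m.N, 0))))
    b0, b1, b2, cp_s = m.subject_params(theta, v, cp, cp_grp, cp_tic, vcp)
    mu = m.mu_from(b0, b1, b2, cp_s, theta, tvc_vals)
    return m.deviance(mu, samples.posterior_mean("sigma2_e"))


def compute_dic(samples: PosteriorSamples) -> tuple[float, float]:
    """Deviance information criterion and its effective-parameter penalty.

    ``pD = mean(deviance) - deviance(at posterior means)``,
    ``DIC = mean(deviance) + pD``.
    """
    if samples.deviance.size == 0:
        raise ValueError("no deviance draws stored")
    dbar = float(samples.deviance.mean())
    pd_eff = dbar - _plugin_deviance(samples)
    return dbar + pd_eff, pd_eff


def posterior_predictive_pvalue(samples: PosteriorSamples,
                                seed: int | np.random.Generator | None = 0,
                                statistic: str = "sum",
                                response: np.ndarray | None = None) -> float:
    """Posterior predictive p-value with a residual discrepancy measure.

    For each kept draw a replicate response vector is simulated from the
    fitted model at that draw (conditional on the drawn random effects) and
    the discrepancy is compared between replicate and observed data.  The
    default discrepancy is the signed sum of residuals ``sum(y - fitted)``;
    ``statistic="ssq"`` uses the sum of squared residuals instead.  Both
    discrepancies have known sampling distributions given a draw, so the
    replicate value is drawn exactly rather than via a full length-N vector.

    ``response`` substitutes an alternative observed vector (same length)
    while keeping the fit frozen; only supported for the sum statistic.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m = samples.model
    n_total = samples.deviance.size
    if n_total < 500:
        warnings.warn("fewer than 500 kept draws; PP p-value is noisy",
                      UserWarning)
    sigma2 = samples.params["sigma2_e"].reshape(-1)
    if statistic == "sum":
        d_obs = samples.sum_resid.reshape(-1).copy()
        if response is not None:
            d_obs += float(np.sum(np.asarray(response) - m.y))
        d_rep = rng.normal(size=n_total) * np.sqrt(m.N * sigma2)
    elif statistic == "ssq":
        if response is not None:
            raise ValueError("response override only supported for statistic='sum'")
        d_obs = samples.ssr.reshape(-1)
        d_rep = sigma2 * rng.chisquare(m.N, size=n_total)
    else:
        raise ValueError("statistic must be 'sum' or 'ssq'")
    return float(np.mean(d_rep >= d_obs))


def group_effect_significant(samples: PosteriorSamples, which: str,
                             level: float = 0.95):
    """Whether the central credible interval of a group shift excludes zero.

    ``which`` is one of ``b0, b1, b2, cp`` (or the sampled parameter name).
    """
    name = _GRP_PARAM.get(which, which)
    if name not in samples.params:
        raise ValueError(
            f"group effect {which!r} is not free under this divergence type")
    lo, hi = samples.credible_interval(name, level)
    return (lo > 0) or (hi < 0), (lo, hi)


@dataclass
class FitComparison:
    """Candidate-suite comparison in the style of a DIC (pD) / PP p-value
    table, plus the selected best model."""

    table: pd.DataFrame
    best_model: str | None
    fits: dict

    def to_json(self):
        return self.table.to_json(orient="records")


def _n_free_group(model_id: str) -> int:
    return len(DIVERGENCE_FREE[MODEL_SUITE[model_id]])


def fit_divergence_suite(ds, model_ids, priors: PriorSet | None = None,
                         config: SamplerConfig | None = None,
                         base_spec: ModelSpec | None = None,
                         keep_fits: bool = True,
                         pp_seed: int = 0,
                         rhat_threshold: float = 1.1) -> FitComparison:
    """Fit candidate divergence models (letters A..H) and rank them.

    The best model has the lowest DIC among converged fits, preferring fits
    whose PP p-value lies in [0.2, 0.8]; near-ties (within 1e-6) go to the
    model with fewer free group shifts.  Non-converged fits (any fixed-effect
    split R-hat above ``rhat_threshold`` when >= 2 chains are run) are
    flagged and excluded from selection with a warning.
    """
    if len(model_ids) < 1:
        raise ValueError("need at least one model id")
    for mid in model_ids:
        if mid not in MODEL_SUITE:
            raise ValueError(f"unknown model id {mid!r}; choose from A..H")
    base = base_spec or ModelSpec(random_effects=("intercept",),
                                  cov_structure="independent")
    config = config or SamplerConfig()
    rows, fits = [], {}
    for mid in model_ids:
        spec = base.with_divergence(MODEL_SUITE[mid])
        samples = sample_posterior(build_model(ds, spec, priors), config)
        dic, pd_eff = compute_dic(samples)
        pp = posterior_predictive_pvalue(samples, seed=pp_seed)
        if config.n_chains >= 2:
            fixed = [n for n in samples.names()
                     if n.startswith(("beta", "cp")) or n == "sigma2_e"]
            rh = samples.rhat()[fixed]
            converged = bool((rh <= rhat_threshold).all())
        else:
            converged = True
        if not converged:
            warnings.warn(f"model {mid} flagged as non-converged", UserWarning)
        rows.append({"model": mid, "label": MODEL_LABELS[mid], "DIC": dic,
                     "pD": pd_eff, "pp_pvalue": pp, "converged": converged,
                     "n_group_params": _n_free_group(mid)})
        if keep_fits:
            fits[mid] = samples
    table = pd.DataFrame(rows)
    cand = table[table.converged]
    if len(cand):
        in_band = cand[(cand.pp_pvalue >= 0.2) & (cand.pp_pvalue <= 0.8)]
        pool = in_band if len(in_band) else cand
        dic_min = pool.DIC.min()
        tied = pool[pool.DIC <= dic_min + 1e-6]
        best = tied.sort_values(["n_group_params", "model"]).iloc[0]["model"]
    else:
        best = None
    return FitComparison(table=table, best_model=best, fits=fits)
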