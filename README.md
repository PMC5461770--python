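# bhpr — Bayesian hierarchical piecewise regression for trajectory divergence

`bhpr` detects and characterises **when and how the trajectories of two
groups of participants diverge** in long-term longitudinal studies, for
continuous outcomes with distinct developmental phases (the motivating case:
child-to-adult BMI in participants who do and do not develop type 2
diabetes).  It implements a hierarchical broken-stick ("random change
point") growth model, the candidate-model suite that distinguishes the
possible divergence mechanisms, and the traditional categorical-mixed-model
LS-means comparator, plus a simulation engine for accelerated longitudinal
designs.

## The model

For participant *i* at age *a<sub>ij</sub>* the response follows a
continuous two-phase linear curve,

```
y_ij = b0_i + b1_i (a_ij − a_ref) + b2_i (a_ij − CP_i)_+  [+ TVC terms] + e_ij ,
e_ij ~ N(0, σ²)
```

with subject-level trajectory parameters decomposed at level 2 as

```
b0_i = β0 + β0_grp G_i + v0_i          (level at the reference age a_ref)
b1_i = β1 + β1_grp G_i + v1_i          (pre-change-point slope)
b2_i = β2 + β2_grp G_i + v2_i          (slope CHANGE after the change point)
CP_i = CP + CP_grp G_i + v_cp_i        (change-point age, raw-age scale)
```

where `G_i ∈ {0,1}` is the group indicator and the `v`'s are random effects
(full, block-diagonal, or independent covariance).  Which group shifts are
free defines the divergence mechanism: a shift in `b2` only (Type I, model
D/F), in `CP` only (Type II, model E), or in both (Type III), within a
suite of candidate models A–H ranked by DIC and checked with posterior
predictive p-values.  The *age at divergence* under a Type II mechanism is
the reference group's `CP`: up to that age the groups share one curve, after
it the later-transitioning group keeps gaining at the childhood rate.

Estimation is Metropolis-within-Gibbs: conjugate updates for everything the
change points leave linear (fixed effects, TIC/TVC coefficients, linear
random effects, Inverse-Gamma/Inverse-Wishart variance components) and
adaptive random-walk Metropolis for the change-point block.  Missing
time-varying covariates are imputed each sweep under a missing-at-random
Gaussian covariate model whose hyperparameters are informed by the observed
entries only.

The LS-means baseline (`bhpr.lsmeans`) fits
`response ~ C(age) × group + (1 | subject)` and reads the divergence age off
the Tukey-adjusted per-age group contrasts, either as the earliest
significant age or as the "midway" cut that best separates non-significant
from significant ages.

## Worked example

Simulate one dataset from the default Type II scenario (100 subjects per
group; generating values β0=26.5, β1=0.67, β2=−0.49, CP=16.02 yr, group CP
shift 12.37 yr, random-intercept variance 2.77, residual variance 2.47) and
fit the generating model:

```python
from bhpr import *

scenario = make_default_paper_scenario((100, 100))
ds, truth = simulate_dataset(scenario, seed=7)

spec = ModelSpec(divergence_type="change_point",
                 random_effects=("intercept",),
                 cov_structure="independent", age_center=25.0)
samples = sample_posterior(build_model(ds, spec, PriorSet()),
                           SamplerConfig(n_chains=2, n_burn=5000,
                                         n_keep=5000, thin=5, seed=1))
print(samples.summary().round(3))
```

```
             mean     sd    q2.5  median   q97.5   rhat
beta0      26.527  0.206  26.124  26.532  26.940  1.002
beta1       0.675  0.015   0.646   0.675   0.705  1.001
beta2      -0.493  0.016  -0.523  -0.493  -0.462  1.000
cp         16.010  0.364  15.283  16.018  16.745  1.002
cp_grp     12.068  0.449  11.180  12.065  12.993  1.000
sigma2_e    2.519  0.115   2.299   2.518   2.756  1.001
sigma2_u0   2.710  0.324   2.152   2.692   3.402  1.000
```

Every generating value sits inside its 95% credible interval: the groups
diverge at `cp` ≈ 16.0 yr and the second group reaches its transition
`cp_grp` ≈ 12.1 yr later.  `compute_dic(samples)` gives DIC = 4689
(pD = 177) and `posterior_predictive_pvalue(samples, seed=1)` = 0.49 —
a p-value near 0.5 indicates an adequate model.  On the same dataset the
LS-means comparator concludes divergence much later (earliest significant
age 21.0, midway 19.5), illustrating its sample-size-driven bias.

The same workflow is available from the shell:

```bash
bhpr simulate --sizes 100,100 --seed 7 --out sim.csv
bhpr fit --data sim.csv --divergence change_point --out fit.json
bhpr suite --data sim.csv --models A,B,C,D,E,F,G,H --out table.csv
bhpr lsmeans --data sim.csv --out lsmeans.csv
bhpr simstudy --reps 20 --seed 1 --out study/
```

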