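import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bhpr import (FixedEffects, LongitudinalDataset, ModelSpec, PriorSet,
                  SamplerConfig, SimScenario, TVCSimModel, build_model,
                  gelman_rubin, run_prior_sensitivity, sample_posterior,
                  simulate_dataset)
from bhpr.sampler import _Chain

from conftest import fast_config


def _spec_e(a_ref=25.0):
    return ModelSpec(divergence_type="change_point",
                     random_effects=("intercept",),
                     cov_structure="independent", age_center=a_ref)


class TestBuildModel:
    def test_type_ii_frees_only_cp_shift(self, small_typeii_fit):
        ds, _, _ = small_typeii_fit
        m = build_model(ds, _spec_e())
        assert m.cp_grp_free
        assert not any(n in m.lin_names
                       for n in ("beta0_grp", "beta1_grp", "beta2_grp"))

    def test_all_four_frees_four_shifts(self, small_typeii_fit):
        ds, _, _ = small_typeii_fit
        m = build_model(ds, _spec_e().with_divergence("all_four"))
        assert m.cp_grp_free
        assert {"beta0_grp", "beta1_grp", "beta2_grp"} <= set(m.lin_names)

    def test_unconditional_matches_ungrouped_parameter_count(self):
        scn = SimScenario(n_group1=10, n_group2=10)
        ds, _ = simulate_dataset(scn, seed=0)
        grouped = build_model(ds, _spec_e().with_divergence("none"))
        plain = ds.with_frame(ds.frame.drop(columns="group"), has_group=False)
        ungrouped = build_model(plain, _spec_e().with_divergence("none"))
        assert grouped.lin_names == ungrouped.lin_names
        assert not grouped.cp_grp_free

    def test_group_required_when_divergence_needs_it(self, toy_dataset):
        with pytest.raises(ValueError, match="group"):
            build_model(toy_dataset, _spec_e(a_ref=9.0))


class TestDegenerateRecovery:
    def test_near_noiseless_data_recovers_truth_within_1pct(self):
        scn = SimScenario(n_group1=30, n_group2=30, var_u0=0.0, var_e=1e-4)
        ds, truth = simulate_dataset(scn, seed=1)
        samples = sample_posterior(build_model(ds, _spec_e()),
                                   fast_config(seed=3))
        for name, true_val in (("beta0", 26.5), ("beta1", 0.67),
                               ("beta2", -0.49), ("cp", 16.02),
                               ("cp_grp", 12.37)):
            est = samples.posterior_mean(name)
            assert abs(est - true_val) <= 0.01 * abs(true_val), name


class TestPriorOnly:
    def test_empty_dataset_returns_prior_moments(self):
        frame = pd.DataFrame(columns=["subject", "age", "response", "group"])
        ds = LongitudinalDataset(frame=frame, has_group=True,
                                 age_window=(6.0, 49.0))
        spec = ModelSpec(divergence_type="intercept_only", random_effects=(),
                         age_center=25.0)
        samples = sample_posterior(
            build_model(ds, spec, PriorSet()),
            SamplerConfig(n_chains=2, n_burn=500, n_keep=2000, thin=1, seed=0))
        draws = samples.draws("beta0_grp")
        sd = 100.0  # prior N(0, 1e4)
        assert abs(draws.mean()) < 4 * sd / np.sqrt(draws.size)
        assert abs(draws.std(ddof=1) - sd) / sd < 0.05


class TestConjugateUpdates:
    def test_fixed_effect_conditional_matches_closed_form(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"subject": [f"s{i}" for i in range(20)],
                              "age": rng.uniform(6, 49, 20),
                              "response": rng.normal(20, 2, 20)})
        ds = LongitudinalDataset(frame=frame)
        spec = ModelSpec(divergence_type="none", random_effects=(),
                         linear_only=True, age_center=25.0)
        model = build_model(ds, spec, PriorSet())
        cfg = SamplerConfig(n_chains=1, n_burn=10, n_keep=10, thin=1, seed=1)
        ch = _Chain(model, cfg, np.random.SeedSequence(1))
        ch.sigma2 = 2.0
        K = 4000
        draws = np.empty((K, model.p))
        for k in range(K):
            ch.update_theta()
            draws[k] = ch.theta
        # independent closed form: ridge posterior of y ~ N(X theta, sigma2)
        X = np.column_stack([np.ones(20), frame.age - 25.0])
        A = X.T @ X / 2.0 + np.eye(2) / 1e4
        m = np.linalg.solve(A, X.T @ frame.response.to_numpy() / 2.0)
        cov = np.linalg.inv(A)
        se = np.sqrt(np.diag(cov) / K)
        np.testing.assert_array_less(np.abs(draws.mean(0) - m), 5 * se)
        np.testing.assert_allclose(np.cov(draws.T), cov, rtol=0.15)

    def test_sigma2_stationary_marginal_matches_analytic_invgamma(self):
        # 1-subject data, fixed effects pinned by a near-point-mass prior:
        # the sigma^2 kept draws must follow the analytic IG posterior.
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 10)
        frame = pd.DataFrame({"subject": "s0", "age": np.linspace(6, 40, 10),
                              "response": y})
        ds = LongitudinalDataset(frame=frame)
        spec = ModelSpec(divergence_type="none", random_effects=(),
                         linear_only=True, age_center=20.0)
        priors = PriorSet(beta_var=1e-12)
        samples = sample_posterior(
            build_model(ds, spec, priors),
            SamplerConfig(n_chains=1, n_burn=500, n_keep=5000, thin=1, seed=2))
        draws = samples.draws("sigma2_e")
        a = 0.001 + 5.0
        b = 0.001 + 0.5 * float(y @ y)
        ks = stats.kstest(draws, stats.invgamma(a, scale=b).cdf)
        assert ks.pvalue > 0.01


class TestRecoveryAndDeterminism:
    def test_generating_effects_inside_95ci_in_most_replicates(self):
        scn = SimScenario()  # published Type II condition, 100/100
        names_truth = {"beta0": 26.5, "beta1": 0.67, "beta2": -0.49,
                       "cp": 16.02, "cp_grp": 12.37}
        hits = {n: 0 for n in names_truth}
        n_reps = 30
        for rep in range(n_reps):
            ds, _ = simulate_dataset(scn, seed=1000 + rep)
            samples = sample_posterior(build_model(ds, _spec_e()),
                                       fast_config(seed=rep))
            for n, tv in names_truth.items():
                lo, hi = samples.credible_interval(n)
                hits[n] += lo <= tv <= hi
        for n, h in hits.items():
            assert h >= 0.9 * n_reps, (n, h)

    def test_identical_config_gives_bitwise_identical_draws(self):
        scn = SimScenario(n_group1=15, n_group2=15)
        ds, _ = simulate_dataset(scn, seed=8)
        cfg = SamplerConfig(n_chains=2, n_burn=200, n_keep=200, thin=2, seed=9)
        a = sample_posterior(build_model(ds, _spec_e()), cfg)
        b = sample_posterior(build_model(ds, _spec_e()), cfg)
        for name in a.names():
            np.testing.assert_array_equal(a.params[name], b.params[name])

    def test_subject_change_points_stay_inside_age_window(self):
        # the sampler asserts the truncation on every draw; this exercises it
        scn = SimScenario(n_group1=20, n_group2=20, var_cp=2.0)
        ds, _ = simulate_dataset(scn, seed=5)
        spec = ModelSpec(divergence_type="change_point",
                         random_effects=("intercept", "cp"),
                         cov_structure="independent", age_center=25.0)
        samples = sample_posterior(
            build_model(ds, spec),
            SamplerConfig(n_chains=1, n_burn=400, n_keep=400, thin=2, seed=6))
        lo, hi = ds.age_window
        cp_mean = samples.posterior_mean("cp")
        assert lo <= cp_mean <= hi
        assert np.isfinite(samples.re_means["cp"]).all()


class TestGelmanRubin:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=100)
        r = gelman_rubin({"x": np.stack([chain, chain])})
        assert r["x"] == pytest.approx(1.0, abs=1e-12)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        arr = np.stack([rng.normal(0, 1, 1000), rng.normal(5, 1, 1000)])
        r = gelman_rubin({"x": arr})
        assert r["x"] > 2
        assert r.attrs["flagged"] == ["x"]

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(size=(4, 100)) + rng.normal(0, 0.3, size=(4, 1))
        # independent textbook computation of the PSRF
        m, n = arr.shape
        W = arr.var(axis=1, ddof=1).mean()
        B = n * np.var(arr.mean(axis=1), ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        got = gelman_rubin({"x": arr})["x"]
        assert got == pytest.approx(max(expected, 1.0), abs=1e-10)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            gelman_rubin({"x": np.zeros((1, 100))})


class TestTVCImputation:
    def test_mar_missing_tvc_coefficient_recovered(self):
        scn = SimScenario(n_group1=60, n_group2=60,
                          tvc=TVCSimModel(beta=1.0, missing_rate=0.17))
        ds, truth = simulate_dataset(scn, seed=21)
        spec = ModelSpec(divergence_type="change_point",
                         random_effects=("intercept",),
                         cov_structure="independent", age_center=25.0,
                         tvc_terms=("tvc",))
        samples = sample_posterior(build_model(ds, spec), fast_config(seed=4))
        est = samples.posterior_mean("beta_tvc[tvc]")
        sd = samples.draws("beta_tvc[tvc]").std(ddof=1)
        assert abs(est - 1.0) <= 2 * sd

    def test_no_missing_values_skip_imputation_machinery(self):
        scn = SimScenario(n_group1=10, n_group2=10,
                          tvc=TVCSimModel(missing_rate=0.0))
        ds, _ = simulate_dataset(scn, seed=3)
        spec = ModelSpec(divergence_type="change_point",
                         random_effects=("intercept",),
                         cov_structure="independent", age_center=25.0,
                         tvc_terms=("tvc",))
        cfg = SamplerConfig(n_chains=1, n_burn=100, n_keep=100, thin=1, seed=0)
        samples = sample_posterior(build_model(ds, spec), cfg)
        assert not any(n.startswith("tvc_mu") for n in samples.names())

    def test_all_missing_tvc_warns_and_still_fits(self):
        scn = SimScenario(n_group1=8, n_group2=8,
                          tvc=TVCSimModel(missing_rate=0.0))
        ds, _ = simulate_dataset(scn, seed=3)
        frame = ds.frame.copy()
        frame["tvc"] = np.nan
        ds = ds.with_frame(frame)
        spec = ModelSpec(divergence_type="change_point",
                         random_effects=("intercept",),
                         cov_structure="independent", age_center=25.0,
                         tvc_terms=("tvc",))
        with pytest.warns(UserWarning, match="entirely missing"):
            model = build_model(ds, spec)
        cfg = SamplerConfig(n_chains=1, n_burn=100, n_keep=100, thin=1, seed=0)
        samples = sample_posterior(model, cfg)
        assert np.isfinite(samples.draws("beta_tvc[tvc]")).all()


class TestPriorSensitivity:
    def test_identical_sets_identical_and_vague_sets_close(self):
        scn = SimScenario(n_group1=30, n_group2=30)
        ds, _ = simulate_dataset(scn, seed=13)
        sets = [PriorSet(), PriorSet(), PriorSet(beta_var=1e6)]
        res = run_prior_sensitivity(ds, _spec_e(), sets,
                                    config=fast_config(seed=1))
        assert len(res.table) == 3
        pd.testing.assert_series_equal(res.table.iloc[0], res.table.iloc[1],
                                       check_names=False)
        # 1e4 vs 1e6 prior variance: posterior means nearly unchanged
        sd = res.fits[0].draws("cp_grp").std(ddof=1)
        diff = abs(res.table.loc[0, "cp_grp"] - res.table.loc[2, "cp_grp"])
        assert diff < 0.3 * sd
        assert res.best_index in (0, 1, 2)

    def test_fewer_than_two_sets_rejected(self, small_typeii_fit):
        ds, _, _ = small_typeii_fit
        with pytest.raises(ValueError, match="2 prior sets"):
            run_prior_sensitivity(ds, _spec_e(), [PriorSet()])
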