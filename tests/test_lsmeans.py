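import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from bhpr import (LongitudinalDataset, SimScenario, earliest_significant_age,
                  fit_categorical_mixed, midway_divergence_age,
                  simulate_dataset, tukey_pairwise)
from bhpr.lsmeans import LsmeansResult, _range_param


def balanced_toy(gap_at_age2=1.0, noise=0.0, n_per_cell=8, seed=0):
    """Two visit ages, two groups, subject random intercepts optional."""
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for g in (0, 1):
        for _ in range(n_per_cell):
            base = rng.normal(0, noise)
            rows.append({"subject": f"s{sid}", "age": 1.0, "group": g,
                         "response": 10.0 + base + rng.normal(0, noise)})
            rows.append({"subject": f"s{sid}", "age": 2.0, "group": g,
                         "response": 12.0 + gap_at_age2 * g + base
                         + rng.normal(0, noise)})
            sid += 1
    return LongitudinalDataset(frame=pd.DataFrame(rows), has_group=True)


def fake_result(ages, p_adj):
    ctr = pd.DataFrame({"age": ages, "estimate": 1.0, "se": 0.1,
                        "t": 10.0, "df": 50, "p_unadj": p_adj,
                        "p_adj": p_adj})
    return LsmeansResult(means=pd.DataFrame(), contrasts=ctr)


class TestCategoricalMixed:
    def test_noiseless_contrasts_recover_gap(self):
        res = fit_categorical_mixed(balanced_toy(gap_at_age2=1.0, noise=1e-8))
        est = res.contrasts.set_index("age")["estimate"]
        assert est[1.0] == pytest.approx(0.0, abs=1e-6)
        assert est[2.0] == pytest.approx(1.0, abs=1e-6)

    def test_lsmeans_equal_raw_cell_means_when_balanced(self):
        ds = balanced_toy(noise=0.5, seed=3)
        res = fit_categorical_mixed(ds)
        df = ds.frame
        for _, row in res.means.iterrows():
            raw = df[(df.age == row.age) & (df.group == row.group)] \
                .response.mean()
            assert row.lsmean == pytest.approx(raw, abs=1e-6)

    def test_alternate_optimizer_agrees(self):
        scn = SimScenario(n_group1=30, n_group2=30)
        ds, _ = simulate_dataset(scn, seed=17)
        a = fit_categorical_mixed(ds, optimizer="lbfgs")
        b = fit_categorical_mixed(ds, optimizer="cg")
        np.testing.assert_allclose(a.means.lsmean, b.means.lsmean, atol=1e-4)
        np.testing.assert_allclose(a.contrasts.estimate, b.contrasts.estimate,
                                   atol=1e-4)

    def test_single_group_age_level_excluded_with_warning(self):
        ds = balanced_toy(noise=0.1)
        extra = ds.frame.iloc[[0]].copy()
        extra["age"] = 3.0  # age 3 observed in group 0 only
        ds2 = LongitudinalDataset(frame=pd.concat([ds.frame, extra]),
                                  has_group=True)
        with pytest.warns(UserWarning, match="only one group"):
            res = fit_categorical_mixed(ds2)
        assert 3.0 not in set(res.contrasts.age)
        assert res.excluded_ages == (3.0,)


class TestTukey:
    def test_adjusted_p_never_below_unadjusted(self):
        ds = balanced_toy(noise=0.5, seed=5)
        res = tukey_pairwise(fit_categorical_mixed(ds))
        assert (res.contrasts.p_adj >= res.contrasts.p_unadj - 1e-12).all()

    def test_identical_contrasts_get_identical_adjusted_p(self):
        res = tukey_pairwise(fake_result([1.0, 2.0, 3.0], [0.5, 0.5, 0.5]))
        p = res.contrasts.p_adj
        assert p.nunique() == 1

    def test_single_contrast_unadjusted(self):
        res = tukey_pairwise(fake_result([1.0], [0.2]))
        row = res.contrasts.iloc[0]
        from scipy.stats import t as t_dist
        assert row.p_adj == pytest.approx(2 * t_dist.sf(abs(row.t), row.df),
                                          rel=1e-9)

    def test_matches_published_studentized_range_quantile(self):
        # R: qtukey(0.95, nmeans=3, df=10) = 3.876777 -> adjusted p = 0.05
        ctr = pd.DataFrame({"age": [1.0, 2.0, 3.0], "estimate": 1.0,
                            "se": 1.0, "t": [3.876777 / np.sqrt(2)] * 3,
                            "df": 10, "p_unadj": 0.01})
        res = tukey_pairwise(LsmeansResult(means=pd.DataFrame(),
                                           contrasts=ctr))
        assert _range_param(3) == 3
        np.testing.assert_allclose(res.contrasts.p_adj, 0.05, atol=1e-3)


class TestDivergenceAges:
    def test_earliest_takes_first_significant(self):
        res = fake_result([12, 15, 18, 21], [0.3, 0.2, 0.04, 0.01])
        assert earliest_significant_age(res) == 18

    def test_earliest_is_literal_even_when_nonmonotone(self):
        res = fake_result([12, 15, 18], [0.04, 0.3, 0.01])
        assert earliest_significant_age(res) == 12

    def test_none_when_nothing_significant(self):
        res = fake_result([12, 15, 18], [0.3, 0.5, 0.9])
        assert earliest_significant_age(res) is None
        assert midway_divergence_age(res) is None

    def test_midway_clean_split(self):
        res = fake_result([12, 15, 18, 21], [0.3, 0.2, 0.04, 0.01])
        assert midway_divergence_age(res) == 16.5

    def test_midway_tolerates_early_isolated_significance(self):
        res = fake_result([12, 15, 18, 21], [0.04, 0.3, 0.01, 0.02])
        assert midway_divergence_age(res) == 16.5

    def test_midway_matches_brute_force_over_cuts(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.integers(2, 9)
            ages = np.sort(rng.choice(np.arange(6, 50), m, replace=False)) \
                .astype(float)
            p = rng.choice([0.01, 0.3], size=m)
            res = fake_result(ages, p)
            got = midway_divergence_age(res)
            sig = p < 0.05
            if not sig.any():
                assert got is None
                continue
            if sig.all():
                assert got == ages[0]
                continue
            best, best_cost = None, np.inf
            for c in range(1, m):
                cost = sig[:c].sum() + (~sig[c:]).sum()
                if cost < best_cost:
                    best, best_cost = 0.5 * (ages[c - 1] + ages[c]), cost
            assert got == best

    def test_all_significant_returns_first_age(self):
        res = fake_result([12, 15, 18], [0.01, 0.02, 0.03])
        assert midway_divergence_age(res) == 12

    def test_adjusted_p_required(self):
        res = replace(fake_result([12.0], [0.5]),
                      contrasts=fake_result([12.0], [0.5])
                      .contrasts.drop(columns="p_adj"))
        with pytest.raises(ValueError, match="tukey"):
            earliest_significant_age(res)
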