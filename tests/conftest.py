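import numpy as np
import pandas as pd
import pytest

from bhpr import (LongitudinalDataset, ModelSpec, PriorSet, SamplerConfig,
                  SimScenario, build_model, sample_posterior,
                  simulate_dataset)

#: short-chain protocol for replicate-heavy tests (point estimates only)
FAST = dict(n_chains=2, n_burn=1500, n_keep=1500, thin=3)


def fast_config(seed=0, **kw):
    return SamplerConfig(**{**FAST, "seed": seed, **kw})


def toy_frame(n_subj=3, ages=(6.0, 9.0, 12.0), slope=0.5, intercept=15.0):
    rows = []
    for i in range(n_subj):
        for a in ages:
            rows.append({"subject": f"s{i}", "age": a,
                         "response": intercept + slope * a + 0.1 * i})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_dataset():
    return LongitudinalDataset(frame=toy_frame())


@pytest.fixture(scope="session")
def small_typeii_scenario():
    """Scaled-down Type II condition for replicate tests."""
    return SimScenario(n_group1=50, n_group2=50)


@pytest.fixture(scope="session")
def small_typeii_fit(small_typeii_scenario):
    """One short Type II fit on one small replicate, shared across tests."""
    ds, truth = simulate_dataset(small_typeii_scenario, seed=42)
    spec = ModelSpec(divergence_type="change_point",
                     random_effects=("intercept",),
                     cov_structure="independent",
                     age_center=small_typeii_scenario.a_ref)
    samples = sample_posterior(build_model(ds, spec, PriorSet()),
                               fast_config(seed=5))
    return ds, truth, samples
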