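import io

import pytest

from burden_of_proof.data_model import read_observations
from burden_of_proof.pipeline import run_pair
from burden_of_proof.synthetic_data import (
    TruthSpec,
    default_pair_config,
    generate_pair_dataset,
)


def synthesize(spec: TruthSpec, **config_overrides):
    """Generate a dataset, round-trip it through the CSV reader, return obs + config + truth."""
    frame, truth = generate_pair_dataset(spec)
    config = default_pair_config(spec, **config_overrides)
    buf = io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.17g")
    buf.seek(0)
    observations = read_observations(buf, config)
    return observations, config, truth


def run_synthetic(spec: TruthSpec, **config_overrides):
    observations, config, truth = synthesize(spec, **config_overrides)
    return run_pair(observations, config), truth


@pytest.fixture(scope="session")
def fitted_pair():
    """One representative fitted pipeline (log-linear truth, outliers, heterogeneity)."""
    spec = TruthSpec(
        n_studies=50,
        obs_per_study=3,
        gamma=0.02,
        tau2=0.01,
        outlier_fraction=0.10,
        seed=1,
    )
    result, truth = run_synthetic(spec, n_ensemble=5)
    return result, truth


@pytest.fixture(scope="session")
def observations_small():
    spec = TruthSpec(n_studies=10, obs_per_study=3, seed=7)
    observations, config, truth = synthesize(spec)
    return observations, config, truth
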