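import numpy as np
import pytest

from combatsim.datasets import make_default_dataset

# reduced study size shared across tests: 3 sites x 300 subjects x 30 IDPs,
# target IDP index 15, behavioral noise variance 0.04
REDUCED = dict(n_per_site=300, n_features=30, target_idp=15)


@pytest.fixture(scope="session")
def reduced_dataset():
    """Outlier-free multisite dataset at reduced size (default site effects)."""
    return make_default_dataset(seed=2, **REDUCED)


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """Reduced dataset with near-disjoint site distributions (shift = 8 SD)."""
    return make_default_dataset(seed=2, additive_shift_scale=8.0, **REDUCED)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mini_sweep(tmp_path_factory):
    """Small full-pipeline run: 6 scenarios x 2 quantities x 2 scores."""
    from combatsim.pipeline import ExperimentConfig, run_experiment

    out = tmp_path_factory.mktemp("mini_sweep")
    cfg = ExperimentConfig(
        quantities=[0.01, 0.05],
        scores=[10.0, 40.0],
        master_seed=7,
        output_dir=str(out),
        **REDUCED,
    )
    report = run_experiment(cfg)
    return cfg, report, out


@pytest.fixture(scope="session")
def sweep_report(mini_sweep):
    return mini_sweep[1]
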