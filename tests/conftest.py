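"""Shared fixtures: a session-scoped default synthetic dataset and its
pipeline run, reused by the recovery and end-to-end tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default study conditions: 500 genes, 3 stages x 2 replicates."""
    from promkit.simulate import SimulationConfig, simulate_dataset, write_dataset

    cfg = SimulationConfig(seed=DEFAULT_SEED)
    ds = simulate_dataset(cfg)
    root = tmp_path_factory.mktemp("default_ds")
    write_dataset(ds, root / "data")
    return cfg, ds, root


@pytest.fixture(scope="session")
def default_run(default_dataset):
    """One full pipeline run over the default dataset."""
    from promkit.cli import dataset_pipeline_config
    from promkit.pipeline import run_pipeline

    cfg, ds, root = default_dataset
    pcfg = dataset_pipeline_config(root / "data", root / "wd", seed=DEFAULT_SEED)
    summary = run_pipeline(pcfg)
    return pcfg, ds, summary


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A 60-gene dataset + run for cheaper integration tests."""
    from promkit.cli import dataset_pipeline_config
    from promkit.pipeline import run_pipeline
    from promkit.simulate import SimulationConfig, simulate_dataset, write_dataset

    cfg = SimulationConfig(seed=3, n_genes=60)
    ds = simulate_dataset(cfg)
    root = tmp_path_factory.mktemp("small_ds")
    write_dataset(ds, root / "data")
    pcfg = dataset_pipeline_config(root / "data", root / "wd", seed=3)
    summary = run_pipeline(pcfg)
    return pcfg, ds, summary
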