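from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A 150-animal, 15-sire cohort shared by association tests."""
    from mirsnp_rewire.datagen import PopulationSpec, simulate_pedigree_genotypes

    spec = PopulationSpec(
        n_individuals=150, n_sires=15, maf=(0.07, 0.41, 0.04),
        n_background_markers=2000, seed=7,
    )
    return simulate_pedigree_genotypes(spec)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on a reduced cohort, shared across tests.

    200 animals keep every planted association overwhelmingly powered while
    the whole run stays around a minute.
    """
    from mirsnp_rewire.pipeline import RunConfig, run_pipeline

    workdir = tmp_path_factory.mktemp("demo_run")
    cfg = RunConfig(
        workdir=str(workdir),
        seed=11,
        n_individuals=200,
        n_sires=20,
        n_background_markers=2000,
        n_shuffles=100,
    )
    manifest = run_pipeline(cfg)
    return cfg, manifest
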