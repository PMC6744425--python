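import time

import numpy as np
import pytest

from ndba.design import generate_design
from ndba.pipeline import RunConfig, run_pipeline
from ndba.synth import SyntheticConfig, generate_patterns

ACCEPTANCE_SEED = 2026


@pytest.fixture(scope="session")
def design():
    return generate_design()


@pytest.fixture(scope="session")
def small_design():
    return generate_design(n_per_cluster=2)


@pytest.fixture(scope="session")
def small_patterns(design):
    """Three subjects on a small grid with the default planted structure."""
    cfg = SyntheticConfig(
        n_subjects=3, grid_shape=(10, 5, 5), region_voxels=40, seed=7
    )
    datasets, true = generate_patterns(design, cfg)
    return cfg, datasets, true


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-configuration pipeline run, shared across tests."""
    outdir = tmp_path_factory.mktemp("default_run")
    t0 = time.perf_counter()
    report = run_pipeline(RunConfig(seed=ACCEPTANCE_SEED), outdir=outdir)
    elapsed = time.perf_counter() - t0
    return {"report": report, "outdir": outdir, "elapsed_s": elapsed}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
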