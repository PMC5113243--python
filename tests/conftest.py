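import numpy as np
import pandas as pd
import pytest

from aaastress.phantom import GenerativeModel, PhantomConfig, generate_patient, simulate_cohort
from aaastress.pipeline import RunConfig, run_all


@pytest.fixture(scope="session")
def small_phantom():
    """One modest rendered patient shared across read-only tests."""
    cfg = PhantomConfig(
        n_patients=1, grid_shape=(16, 128, 128), spacing=(3.0, 0.7, 0.7), seed=3
    )
    model = GenerativeModel.multivariate()
    ct, pet, truth = generate_patient(cfg, model, 0)
    return cfg, model, ct, pet, truth


@pytest.fixture(scope="session")
def cohort_table():
    """Analytic 21-patient octant table from the multivariate generator."""
    return simulate_cohort(model=GenerativeModel.multivariate(), seed=42, n_patients=21)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A full deterministic 2-patient pipeline run (shared, read-only)."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        out_dir=str(out),
        seed=11,
        n_patients=2,
        grid_shape=(16, 128, 128),
        spacing=(3.0, 0.7, 0.7),
        interp="nearest",
        rigid_offset_mode="integer_voxel",
        run_backward_elimination=False,
    )
    artifacts = run_all(cfg)
    table = pd.read_csv(out / "octant_table.csv")
    truths = {}
    pcfg = cfg.phantom_config()
    model = GenerativeModel.multivariate()
    for pid in range(cfg.n_patients):
        _, _, truth = generate_patient(pcfg, model, pid)
        truths[pid] = truth
    return cfg, artifacts, table, truths


@pytest.fixture
def rng():
    return np.random.default_rng(0)
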