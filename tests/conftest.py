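import numpy as np
import pytest

import lipidmsi as lm
import lipidmsi.preprocess as pp


@pytest.fixture(scope="session")
def default_phantom():
    """Default-condition phantom (seed 1) with isotope satellites."""
    spec = lm.PhantomSpec(seed=1, isotope_satellites=True)
    datasets, truth = lm.simulate_dataset(spec)
    return spec, datasets, truth


@pytest.fixture(scope="session")
def preprocessed_tables(default_phantom):
    _, datasets, _ = default_phantom
    tables = []
    for ds in datasets:
        t = pp.pick_features(pp.tic_normalize(ds))
        tables.append(pp.deisotope(t))
    return tables


@pytest.fixture(scope="session")
def table1_records():
    return lm.load_table1()


@pytest.fixture(scope="session")
def lipid_db():
    return lm.default_database()


@pytest.fixture()
def small_dataset():
    """A tiny 2x2 grid with a 3-point axis."""
    rng = np.random.default_rng(42)
    return lm.MSIDataset(
        replicate_id="tiny", polarity="negative", width=2, height=2,
        mz_axis=np.array([200.0, 300.0, 400.5]),
        intensities=rng.random((4, 3)).astype(np.float32) * 10 + 0.5,
    )
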