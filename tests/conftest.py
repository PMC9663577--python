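import pytest

from polytereg.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete three-subgenome dataset shared across tests."""
    cfg = SimConfig(subgenome_length=200_000, n_triads=30, n_tfs=3, seed=1)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    small_dataset.write(out)
    return out
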