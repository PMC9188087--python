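import pytest

from visiumview import fixtures, spaceranger_io as srio
from visiumview.core_model import align_gene_universe


@pytest.fixture(scope="session")
def sim_cfg():
    return fixtures.SimConfig(n_array_rows=12, n_array_cols=14, n_genes=120,
                              n_mito_genes=8, n_layers=3, seed=42)


@pytest.fixture(scope="session")
def sim_dir(sim_cfg, tmp_path_factory):
    """A written synthetic Space Ranger directory plus its in-memory truth."""
    path = tmp_path_factory.mktemp("srdir") / "sample"
    truth = fixtures.write_spaceranger_dir(sim_cfg, str(path))
    return str(path), truth


@pytest.fixture(scope="session")
def sample(sim_dir):
    path, _ = sim_dir
    return srio.load_sample(path, "sampleA")


@pytest.fixture(scope="session")
def truth(sim_dir):
    return sim_dir[1]


@pytest.fixture()
def dataset3(sim_cfg, tmp_path):
    """Three samples generated from different seeds, aligned to one universe."""
    samples = []
    for i in range(3):
        cfg = fixtures.SimConfig(**{**sim_cfg.__dict__, "seed": 100 + i})
        d = tmp_path / f"s{i}"
        fixtures.write_spaceranger_dir(cfg, str(d))
        samples.append(srio.load_sample(str(d), f"s{i}"))
    return align_gene_universe(samples)
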