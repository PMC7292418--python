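import numpy as np
import pytest

from vliver.config import LayerSpec, LobuleConfig, default_config
from vliver.fixtures import tiny_band_config, tiny_lobule_config
from vliver.lobule import compute_zonal_positions, sample_lobule_graph
from vliver.transport import LiverLattice


@pytest.fixture(scope="session")
def cfg_default():
    return default_config()


def small_structure_config() -> LobuleConfig:
    """A reduced lobule (~1,500 vHPCs) preserving the default's layer shape."""
    return LobuleConfig(
        layers=[
            LayerSpec((6, 8), (9, 13), (8, 10)),
            LayerSpec((3, 3), (7, 9), (6, 7)),
            LayerSpec((2, 3), (8, 10), (10, 12)),
        ],
        n_lobules_per_liver=1,
    )


@pytest.fixture
def cfg_small(cfg_default):
    """Default mechanism and gradients on a small liver for fast dynamics."""
    cfg = cfg_default.copy()
    cfg.lobule = small_structure_config()
    cfg.dose_objects = 5000
    cfg.duration_cycles = 1200
    cfg.n_trials = 2
    cfg.n_lobules = 1
    cfg.measure_every = 20
    cfg.ledger_check_every = 100
    cfg.validate()
    return cfg


@pytest.fixture
def tiny_chain():
    """Degenerate 3-node chain lobule with zonal positions computed."""
    graph = sample_lobule_graph(tiny_lobule_config(), seed=0)
    return compute_zonal_positions(graph)


@pytest.fixture
def tiny_lattice(tiny_chain):
    return LiverLattice.build([tiny_chain], tiny_band_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
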