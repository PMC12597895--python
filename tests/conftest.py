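import numpy as np
import pytest

import spatialabm as sa


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_table():
    """Nine spatial cells of three measured labels."""
    ids = [f"c{i}" for i in range(9)]
    labels = ["tumor", "tumor", "tumor", "epithelial", "epithelial",
              "Tcell", "Tcell", "Tcell", "fibroblast"]
    xy = np.array(
        [[0, 0], [10, 0], [0, 10], [30, 30], [-30, 30],
         [50, 0], [0, 50], [-50, 0], [100, 100]],
        dtype=float,
    )
    return sa.CellTable(ids, labels, xy)


def make_config(**overrides):
    """Default model config with keyword overrides applied."""
    cfg = sa.default_config()
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def single_type_state(xy, type_name="cancer", config=None, seed=0, partner=None):
    """Hand-built simulation state with all agents of one type."""
    cfg = config or sa.default_config()
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    init = sa.InitialState(
        xy=xy, types=np.array([type_name] * len(xy), dtype=object),
        domain=cfg.domain,
    )
    state = sa.SimulationState.from_initial_state(
        init, cfg, np.random.default_rng(seed)
    )
    if partner is not None:
        state.partner = np.asarray(partner, dtype=np.int64)
    return state
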