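import numpy as np
import pytest

from cbmap.geogrid import downsample, rasterize
from cbmap.synthetic_vineyard import VineyardConfig, generate, grid_for, to_trait_samples


@pytest.fixture(scope="session")
def default_config():
    return VineyardConfig(seed=0)


@pytest.fixture(scope="session")
def field(default_config):
    """Default synthetic field: (sample table, truth record)."""
    return generate(default_config)


def cell_table(config, traits, factor=1):
    """Rasterize sample traits to cells and return aligned non-missing vectors."""
    frame, _ = generate(config)
    grid = grid_for(config)
    maps = {}
    for t in traits:
        m = rasterize(to_trait_samples(frame, t), grid)
        maps[t] = downsample(m, factor) if factor > 1 else m
    ok = np.ones(maps[traits[0]].grid.shape, dtype=bool)
    for m in maps.values():
        ok &= ~m.missing_mask
    return {t: m.values[ok] for t, m in maps.items()}


@pytest.fixture(scope="session")
def default_cells(default_config):
    """Cell-level trait table of the default field at 4 m resolution."""
    return cell_table(default_config, ("X1", "Xy", "X7", "X8", "X9"))
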