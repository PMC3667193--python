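import numpy as np
import pytest

from microcensus import (
    CensusConfig,
    SceneSpec,
    generate_covered_scene,
)

#: Scale used by every synthetic scene in the suite (SceneSpec default).
PPMM = 20.0


@pytest.fixture(scope="session")
def census_config():
    return CensusConfig(pixels_per_mm=PPMM)


@pytest.fixture(scope="session")
def exact_scene():
    """A fully covered, noise-free scene whose 20 organisms never touch.

    Under these conditions the min-projection background is exact and every
    per-frame count must equal the ground truth exactly.
    """
    spec = SceneSpec(seed=42, confine_to_cells=True, cell_margin_px=1.0)
    stack, truth = generate_covered_scene(spec)
    return stack, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20131)
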