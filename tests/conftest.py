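import numpy as np
import pytest
from hypothesis import settings

from phenotrack.tracking import ArenaGeometry

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def box_arena() -> ArenaGeometry:
    """Plain 300x200 px rectangular arena with a single chamber zone."""
    rect = [(0, 0), (300, 0), (300, 200), (0, 200)]
    return ArenaGeometry(
        bounds=rect,
        zones={"chamber": rect},
        px_per_cm=4.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
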