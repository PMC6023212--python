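import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from spheromon.phantom import AggregationParams, PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_well_spec():
    """One fully-visible well in a small frame, compact steady-state blob."""
    ag = AggregationParams(
        n_fragments=1,
        steady_state_area_px2=5000.0,
        steady_state_circularity=1.0,
        rate_per_hour=float("inf"),
        n_holes=0,
    )
    return PhantomSpec(
        image_shape=(300, 300),
        layout_margin=95.0,
        noise_sigma=0.0,
        aggregation=ag,
        seed=3,
    )


def lattice_disk(radius: float, pad: int = 2) -> np.ndarray:
    r_int = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    return xx**2 + yy**2 <= radius**2
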