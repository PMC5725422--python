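import numpy as np
import pytest

from diliforest.io_types import LESS_DILI, MOST_DILI, NO_DILI
from diliforest.synthetic_data import GeneratorSpec, generate


@pytest.fixture(scope="session")
def separable_2class():
    """Strongly separated binary table: 5 informative + 20 noise columns."""
    return generate(
        GeneratorSpec(
            class_sizes={NO_DILI: 60, MOST_DILI: 40},
            d_informative=5,
            d_noise=20,
            effect_size=3.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def noise_2class():
    """Label-independent binary table (null model input)."""
    return generate(
        GeneratorSpec(
            class_sizes={NO_DILI: 60, MOST_DILI: 40},
            d_informative=0,
            d_noise=25,
            seed=7,
        )
    ).table


@pytest.fixture(scope="session")
def small_3class():
    """Moderately separated ternary table."""
    return generate(
        GeneratorSpec(
            class_sizes={NO_DILI: 50, LESS_DILI: 50, MOST_DILI: 50},
            d_informative=4,
            d_noise=20,
            effect_size=2.0,
            seed=3,
        )
    ).table
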