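import numpy as np
import pandas as pd
import pytest

from cfnano.deconvolution import ReferenceAtlas


@pytest.fixture
def toy_atlas() -> ReferenceAtlas:
    """Separable 3-component atlas on 6 probes (no noise)."""
    betas = pd.DataFrame(
        {
            "A": [0.9, 0.1, 0.5, 0.5, 0.5, 0.5],
            "B": [0.5, 0.5, 0.9, 0.1, 0.5, 0.5],
            "C": [0.5, 0.5, 0.5, 0.5, 0.9, 0.1],
        },
        index=[f"cg{i}" for i in range(6)],
    )
    return ReferenceAtlas(betas)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
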