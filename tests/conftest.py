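import numpy as np
import pandas as pd
import pytest

from coexppi.synthetic import SyntheticDesign, generate_expression


@pytest.fixture
def small_design():
    """Three planted modules plus background, desk-scale."""
    return SyntheticDesign(
        n_genes=100,
        n_samples=120,
        module_sizes=(30, 25, 15),
        background_genes=30,
        factor_loading_range=(0.6, 0.9),
        target_genes=("G001", "G002", "G003"),
        seed=7,
    )


@pytest.fixture
def small_world(small_design):
    expr, truth = generate_expression(small_design)
    return small_design, expr, truth


@pytest.fixture
def noise_matrix():
    rng = np.random.default_rng(42)
    return pd.DataFrame(
        rng.standard_normal((50, 80)),
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{i:03d}" for i in range(80)],
    )
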