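import numpy as np
import pandas as pd
import pytest

from triwi import ExpressionMatrix, PlantedTriplet, SyntheticConfig, generate_cohort


def make_matrix(values: np.ndarray, group_labels=None) -> ExpressionMatrix:
    """Wrap a plain array as an ExpressionMatrix with default labels."""
    g, n = values.shape
    genes = [f"g{i}" for i in range(g)]
    samples = [f"s{j}" for j in range(n)]
    if group_labels is None:
        group_labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        pd.Series(group_labels, index=samples, name="group"),
    )


@pytest.fixture
def random_matrix():
    """30 independent-noise genes over 60 samples."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(size=(30, 60)))


@pytest.fixture
def planted_cohort():
    """Study-sized cohort (42/33/28) with one paper-strength planted triplet."""
    config = SyntheticConfig(
        n_genes=30,
        planted_triplets=(PlantedTriplet("Zsw", "Xpa", "Ypa"),),
        seed=7,
    )
    return generate_cohort(config)
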