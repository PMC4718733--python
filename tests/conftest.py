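import numpy as np
import pandas as pd
import pytest

from replicaging import synthdata as sd


@pytest.fixture(scope="session")
def quadrant_truth():
    """1000 genes, 25% per quadrant archetype, no flat genes, no complexes."""
    return sd.generate_molecular_truth(1000, [0.25, 0.25, 0.25, 0.25, 0.0], seed=7)


@pytest.fixture(scope="session")
def small_truth():
    """Small mixed-archetype truth with complexes, for pipeline tests."""
    return sd.generate_molecular_truth(
        200,
        {
            "coupled_up": 0.15,
            "coupled_down": 0.15,
            "uncoupled_protein_up": 0.25,
            "uncoupled_protein_down": 0.10,
            "flat": 0.35,
        },
        n_complexes=6,
        seed=11,
    )


@pytest.fixture()
def spec_W():
    """A 3x3 composition matrix with exact algebraic solution (det != 0)."""
    return pd.DataFrame(
        [[0.8, 0.15, 0.05], [0.3, 0.6, 0.1], [0.05, 0.9, 0.05]],
        index=["mix1", "mix2", "mix3"],
        columns=list(sd.CELL_TYPES),
    )


def random_simplex_matrix(rng, n=3, min_det=1e-3):
    """Random invertible matrix with rows on the simplex."""
    while True:
        W = rng.dirichlet(np.ones(n), size=n)
        if abs(np.linalg.det(W)) > min_det:
            return W
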