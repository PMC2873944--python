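import numpy as np
import pytest

from alinfo import CircuitParams, OdorResponseMatrix, synthesize_orn_matrix


@pytest.fixture(scope="session")
def hallem_like():
    """Synthetic 8-glomerulus x 20-odor ensemble with the measured-data
    signature (most responses weak, a minority strong)."""
    return synthesize_orn_matrix(8, 20, seed=11)


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny 4-glomerulus x 4-odor ensemble for fast end-to-end runs."""
    return synthesize_orn_matrix(4, 4, seed=7)


@pytest.fixture
def params_default():
    return CircuitParams()


@pytest.fixture
def params_peak_i():
    """Concave transformation with inhibitory lateral input."""
    return CircuitParams(beta=0.5, w_lat=-1.0)


@pytest.fixture
def toy_matrix_file(tmp_path):
    """2x3 rate file {0, 10, 50; 5, 0, 250} in tab-delimited layout."""
    path = tmp_path / "toy.tsv"
    path.write_text(
        "receptor\todorA\todorB\todorC\n"
        "or1\t0\t10\t50\n"
        "or2\t5\t0\t250\n"
    )
    return path


def one_hot_matrix(n_glom: int, n_odors: int, rate: float = 400.0,
                   active_per_odor: int = 2) -> OdorResponseMatrix:
    """Odors driving disjoint glomerulus groups hard — near-separable."""
    rates = np.zeros((n_glom, n_odors))
    for s in range(n_odors):
        for k in range(active_per_odor):
            rates[(s * active_per_odor + k) % n_glom, s] = rate
    return OdorResponseMatrix(rates)
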