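import numpy as np
import pytest

from lipevol.io_core import ALPHABET, MultipleAlignment, ProteinRecord
from lipevol.model import build_wag_model, equal_rates_model
from lipevol.simdata import simulate_tree


@pytest.fixture(scope="session")
def wag():
    return build_wag_model("wag_default")


@pytest.fixture(scope="session")
def equal_rates():
    return equal_rates_model()


@pytest.fixture
def small_msa():
    return MultipleAlignment(
        [
            ProteinRecord("a", "ARNDC"),
            ProteinRecord("b", "ARNEC"),
            ProteinRecord("c", "GRN-C"),
            ProteinRecord("d", "ARXDC"),
        ]
    )


def random_sequences(rng, n, length):
    letters = np.array(list(ALPHABET))
    return ["".join(letters[rng.integers(20, size=length)]) for _ in range(n)]


@pytest.fixture
def random_tree_factory():
    def make(n_leaves, seed, mean_branch_length=0.3):
        return simulate_tree(
            n_leaves, mean_branch_length=mean_branch_length, seed=seed
        )

    return make
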