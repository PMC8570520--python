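import numpy as np
import pytest

from codondecay import (
    CodingSequence,
    SyntheticGeneSpec,
    example_fitness_table,
    generate_coding,
    k2p_model,
    random_context_model,
)


@pytest.fixture(scope="session")
def table():
    return example_fitness_table()


@pytest.fixture(scope="session")
def k2p():
    return k2p_model()


@pytest.fixture(scope="session")
def context_model():
    return random_context_model(np.random.default_rng(20240901))


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture(scope="session")
def optimal_ancestor(table) -> CodingSequence:
    """A 120-codon gene built entirely of w = 1 codons (CAI exactly 1)."""
    return generate_coding(
        SyntheticGeneSpec(n_codons=120, beta=1e6, seed=42), table, "ancestor"
    )


def random_count_matrices(rng, low=0, high=200):
    """Random raw 16-context count matrices (positive diagonals)."""
    from codondecay.counting import ALL_CONTEXTS

    raw = {}
    for ctx in ALL_CONTEXTS:
        m = rng.integers(low, high, size=(4, 4))
        m[np.diag_indices(4)] += 50  # keep every row total positive
        raw[ctx] = m.astype(np.int64)
    return raw
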