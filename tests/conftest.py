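import numpy as np
import pytest

from mbcdeg import (
    CountMatrix,
    design_from_labels,
    fig2_scenario,
    simulate_counts,
)


@pytest.fixture
def design_5v6():
    return design_from_labels(["A"] * 5 + ["B"] * 6)


@pytest.fixture
def design_3v3():
    return design_from_labels(["A"] * 3 + ["B"] * 3)


@pytest.fixture
def fig2_dataset():
    """One draw of the canonical worked-example scenario."""
    return simulate_counts(fig2_scenario(seed=1))


@pytest.fixture
def null_dataset_5v6():
    """A DEG-free dataset at the worked-example design."""
    from mbcdeg import SimulationScenario

    return simulate_counts(
        SimulationScenario(G=2000, n_a=5, n_b=6, p_deg=0.0, p_a=0.5, seed=21)
    )


def random_count_matrix(rng, G=None, J=None, mean=50.0):
    """Small random Poisson count matrix for oracle comparisons."""
    G = G if G is not None else int(rng.integers(15, 60))
    J = J if J is not None else int(rng.integers(2, 6))
    vals = rng.poisson(mean * rng.lognormal(0, 0.6, size=(G, 1)), size=(G, J))
    vals[0] = np.maximum(vals[0], 1)  # avoid an all-zero column in tiny matrices
    return CountMatrix(
        tuple(f"g{i}" for i in range(G)),
        tuple(f"s{j}" for j in range(J)),
        vals.astype(np.int64),
    )
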