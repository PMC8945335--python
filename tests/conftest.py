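import numpy as np
import pytest

from issrpop.marker_data import MarkerMatrix


@pytest.fixture
def tiny_matrix():
    """3 individuals x 4 loci, 2 populations."""
    return MarkerMatrix(
        individual_ids=["a1", "a2", "b1"],
        locus_ids=["L1", "L2", "L3", "L4"],
        bands=np.array([[1, 0, 1, 1], [1, 1, 0, 1], [0, 1, 1, 0]]),
        pop_of={"a1": "A", "a2": "A", "b1": "B"},
    )


@pytest.fixture
def amova_toy():
    """2 populations x 4 individuals x 3 loci; printed fixture for the
    sums-of-squares oracle."""
    bands = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [1, 1, 1],
            [1, 1, 0],
            [0, 0, 1],
            [0, 1, 1],
            [0, 0, 1],
            [1, 0, 1],
        ]
    )
    ids = [f"i{k}" for k in range(8)]
    pop_of = {f"i{k}": ("A" if k < 4 else "B") for k in range(8)}
    return MarkerMatrix(ids, ["L1", "L2", "L3"], bands, pop_of)


@pytest.fixture
def three_pop_matrix():
    """3 populations x 4 individuals x 5 loci with a private band in C."""
    rng = np.random.default_rng(7)
    bands = (rng.random((12, 5)) < 0.5).astype(int)
    bands[:, 4] = 0
    bands[8:, 4] = [1, 1, 0, 1]  # band private to population C
    ids = [f"x{k}" for k in range(12)]
    pops = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    return MarkerMatrix(ids, [f"L{j}" for j in range(5)], bands, dict(zip(ids, pops)))
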