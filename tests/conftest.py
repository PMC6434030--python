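import numpy as np
import pandas as pd
import pytest

from biofilm_assembly.io import CommunityTable


@pytest.fixture
def toy_table() -> CommunityTable:
    """Two groups of two samples, six taxa, hand-set counts."""
    counts = pd.DataFrame(
        [
            [5, 3, 0, 1, 0, 0],
            [4, 2, 1, 0, 0, 0],
            [0, 1, 2, 3, 4, 0],
            [0, 0, 3, 2, 5, 1],
        ],
        index=["a1", "a2", "b1", "b2"],
        columns=[f"t{i}" for i in range(6)],
    )
    groups = {"a1": "G1", "a2": "G1", "b1": "G2", "b2": "G2"}
    return CommunityTable(counts, groups)


def random_table(rng: np.random.Generator, n_samples=8, n_taxa=30) -> CommunityTable:
    """Random sparse count table with two equal groups (helper, not a fixture)."""
    counts = rng.poisson(2.0, size=(n_samples, n_taxa))
    counts[rng.random(counts.shape) < 0.4] = 0
    counts[:, 0] += 1  # no empty samples
    half = n_samples // 2
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
    groups = {f"s{i}": ("G1" if i < half else "G2") for i in range(n_samples)}
    return CommunityTable(frame, groups, quiet=True)
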