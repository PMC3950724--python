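import numpy as np
import pytest

from ganet import ExpressionMatrix


@pytest.fixture
def toy_matrix():
    """3 genes x 4 chips with simple hand-checkable values."""
    return ExpressionMatrix(
        gene_ids=["gA", "gB", "gC"],
        sample_ids=["c1", "c2", "c3", "c4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [1.5, 0.5, 2.5, 2.0],
            ]
        ),
    )


@pytest.fixture
def random_matrix():
    """Factory for seeded random expression matrices."""

    def make(n=20, m=30, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            gene_ids=[f"g{i:03d}" for i in range(n)],
            sample_ids=[f"s{j:03d}" for j in range(m)],
            values=rng.normal(size=(n, m)),
        )

    return make


def planted_condition_matrix(seed, n_noise=190, n_planted=10):
    """Two-gene fixture for the condition-removal test.

    Gene ``a`` is continuous noise; gene ``b`` is silent (baseline 0)
    except on the planted chips, where both genes are strongly co-elevated
    at a common plateau.  Only planted-chip removals reduce the pair's MI,
    and by construction all ten reductions are identical.
    """
    rng = np.random.default_rng(seed)
    m = n_noise + n_planted
    x = rng.normal(size=m)
    y = np.zeros(m)
    x[:n_planted] = 6.0
    y[:n_planted] = 1.0
    return ExpressionMatrix(
        gene_ids=["a", "b"],
        sample_ids=[f"chip{i:03d}" for i in range(m)],
        values=np.vstack([x, y]),
    )
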