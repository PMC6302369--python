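import numpy as np
import pytest

from mmtsne import MultiMapEmbedding


def random_joint_p(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random valid joint distribution: symmetric, zero diagonal, sums to 1."""
    P = rng.random((n, n))
    P = 0.5 * (P + P.T)
    np.fill_diagonal(P, 0.0)
    return P / P.sum()


def random_embedding(
    n: int, M: int, rng: np.random.Generator, scale: float = 1.0
) -> MultiMapEmbedding:
    ids = tuple(f"p{i}" for i in range(n))
    return MultiMapEmbedding(
        ids=ids,
        Y=rng.normal(scale=scale, size=(n, M, 2)),
        Omega=rng.normal(size=(n, M)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# the 4-phenotype similarity block used throughout: AS/MOWS/HWS/EVAS with
# intransitive zeros (AS~MOWS, AS~EVAS, MOWS~HWS, HWS~EVAS; other pairs 0)
PHENOTYPE_IDS = ("AS", "MOWS", "HWS", "EVAS")
PHENOTYPE_SIM = np.array(
    [
        [1.0, 0.5957, 0.0, 0.5148],
        [0.5957, 1.0, 0.5298, 0.0],
        [0.0, 0.5298, 1.0, 0.5392],
        [0.5148, 0.0, 0.5392, 1.0],
    ]
)
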