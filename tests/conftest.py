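import numpy as np
import pytest

from bgcmf.data_io import AssociationMatrix, SimilarityMatrix


def random_binary(rng, n, m, density=0.3) -> np.ndarray:
    return (rng.random((n, m)) < density).astype(float)


def random_similarity(rng, q) -> np.ndarray:
    """Random symmetric matrix in [0, 1] with unit diagonal."""
    E = rng.random((q, q))
    S = np.clip((E + E.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def make_association(values, prefix=("m", "d")) -> AssociationMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return AssociationMatrix(
        values,
        tuple(f"{prefix[0]}{i}" for i in range(n)),
        tuple(f"{prefix[1]}{j}" for j in range(m)),
    )


def make_similarity(values, kind, prefix=None) -> SimilarityMatrix:
    values = np.asarray(values, dtype=float)
    if prefix is None:
        prefix = "m" if kind == "miRNA" else "d"
    return SimilarityMatrix(values, tuple(f"{prefix}{i}" for i in range(values.shape[0])), kind)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
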