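import numpy as np
import pytest

from tscca import CorrelationTensor, ExpressionMatrix, standardize_columns


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_tensor(rng):
    """Random 5 × 4 × 3 tensor with correlation-scale entries."""
    values = rng.uniform(-0.9, 0.9, size=(5, 4, 3))
    return CorrelationTensor(
        values,
        [f"g{i}" for i in range(5)],
        [f"m{j}" for j in range(4)],
        [f"c{k}" for k in range(3)],
    )


@pytest.fixture
def expression_pair(rng):
    """One cancer's matched (X, Y), standardized, 30 samples."""
    n, p, q = 30, 6, 4
    X = ExpressionMatrix(rng.standard_normal((n, p)),
                         [f"s{t}" for t in range(n)],
                         [f"g{i}" for i in range(p)])
    Y = ExpressionMatrix(rng.standard_normal((n, q)),
                         [f"s{t}" for t in range(n)],
                         [f"m{j}" for j in range(q)])
    return standardize_columns(X), standardize_columns(Y)


def sparse_rank1_tensor(p, q, M, I, J, K, d, seed=0, gauge_positive=True):
    """Exact d·(u∘v∘w) with given supports and unit factors."""
    rng = np.random.default_rng(seed)

    def unit_on(n, S):
        x = np.zeros(n)
        vals = rng.uniform(0.5, 1.0, size=len(S)) * rng.choice([-1, 1], size=len(S))
        x[list(S)] = vals
        return x / np.linalg.norm(x)

    u = unit_on(p, I)
    v = unit_on(q, J)
    w = unit_on(M, K)
    if gauge_positive:
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            u, v = -u, -v
    T = d * np.einsum("i,j,k->ijk", u, v, w)
    return T, u, v, w
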