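import numpy as np
import pytest

from gwascomp.datatypes import ExpressionMatrix


@pytest.fixture(scope="session")
def planted_expr():
    """3 planted co-expression blocks of 8 genes (within-block cor ~0.9)."""
    rng = np.random.default_rng(0)
    n = 200
    rows = []
    for _ in range(3):
        latent = rng.standard_normal(n)
        for _ in range(8):
            rows.append(np.sqrt(0.9) * latent + np.sqrt(0.1) * rng.standard_normal(n))
    return ExpressionMatrix(
        [f"g{i:02d}" for i in range(24)], [f"s{j}" for j in range(n)], np.array(rows)
    )


@pytest.fixture(scope="session")
def planted_labels():
    """True block membership of the planted_expr fixture."""
    return np.repeat([1, 2, 3], 8)


def orthonormal_profiles(n: int, k: int, seed: int = 0) -> np.ndarray:
    """k centered, orthonormal sample profiles of length n (building blocks
    for expression rows with exactly prescribed sample correlations)."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n, k + 1))
    base[:, 0] = 1.0  # project out the constant -> centered columns
    q, _ = np.linalg.qr(base)
    return q[:, 1 : k + 1].T
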