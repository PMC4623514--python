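import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repo",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repo")


def brute_force_energy(lattice, kernel):
    """O(N * K) pair enumeration of the Hamiltonian, independent of the
    vectorized implementation: loop over every site and every offset, count
    each unordered pair twice and halve."""
    L = lattice.linear_size
    s = lattice.spins
    e = 0.0
    for i in range(L):
        for j in range(L):
            for di, dj, w in zip(kernel.d_rows, kernel.d_cols, kernel.weights):
                e += w * s[i, j] * s[(i + di) % L, (j + dj) % L]
    return -0.5 * e


def brute_force_pair_correlation(arrays):
    """O(N^2) direct <s_i s_{i+r}> over all separations and an ensemble."""
    L = arrays[0].shape[0]
    acc = np.zeros((L, L))
    for a in arrays:
        for di in range(L):
            for dj in range(L):
                acc[di, dj] += np.mean(a * np.roll(a, (-di, -dj), axis=(0, 1)))
    return acc / len(arrays)


@pytest.fixture(scope="session")
def kernel_n6():
    from lrising import build_coupling_kernel

    return build_coupling_kernel(6.0)


@pytest.fixture(scope="session")
def kernel_n12():
    from lrising import build_coupling_kernel

    return build_coupling_kernel(12.0)
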