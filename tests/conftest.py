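import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rayoa import FixtureSpec, make_enantiomer_pair, make_tensor_set

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20251204)


@pytest.fixture
def chiral_set():
    return make_tensor_set(FixtureSpec(seed=7))


@pytest.fixture
def enantiomer_pair():
    return make_enantiomer_pair(FixtureSpec(seed=11))


@pytest.fixture
def mirror_set():
    return make_tensor_set(FixtureSpec(seed=13, chirality="achiral-mirror"))


# ---------------------------------------------------------------------------
# Independent brute-force oracles: explicit index loops, no shared code with
# the package's einsum implementations.
# ---------------------------------------------------------------------------

def eps(i, j, k):
    """Levi-Civita symbol by explicit permutation parity."""
    return ((i - j) * (j - k) * (k - i)) // 2


def beta2_oracle(alpha):
    s1 = 0.0
    for i in range(3):
        for j in range(3):
            s1 += alpha[i, j] * alpha[i, j]
    tr = alpha[0, 0] + alpha[1, 1] + alpha[2, 2]
    return 0.5 * (3.0 * s1 - tr * tr)


def betaG2_oracle(alpha, gprime):
    s1 = 0.0
    for i in range(3):
        for j in range(3):
            s1 += alpha[i, j] * gprime[i, j]
    tra = alpha[0, 0] + alpha[1, 1] + alpha[2, 2]
    trg = gprime[0, 0] + gprime[1, 1] + gprime[2, 2]
    return 0.5 * (3.0 * s1 - tra * trg)


def betaA2_oracle(alpha, aquad, omega):
    s = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    s += alpha[i, j] * eps(i, k, l) * aquad[k, l, j]
    return 0.5 * omega * s


def transform_oracle(alpha, gprime, aquad, r):
    """Componentwise transformation loops (polar rank 2/3, axial rank 2)."""
    det = np.linalg.det(r)
    a_new = np.zeros((3, 3))
    g_new = np.zeros((3, 3))
    q_new = np.zeros((3, 3, 3))
    for i in range(3):
        for j in range(3):
            for a in range(3):
                for b in range(3):
                    a_new[i, j] += r[i, a] * r[j, b] * alpha[a, b]
                    g_new[i, j] += det * r[i, a] * r[j, b] * gprime[a, b]
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for a in range(3):
                    for b in range(3):
                        for c in range(3):
                            q_new[i, j, k] += (r[i, a] * r[j, b] * r[k, c]
                                               * aquad[a, b, c])
    return a_new, g_new, q_new
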