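"""Shared fixtures and independent oracles.

The oracles evaluate the update rules and the divergence with explicit
nested Python loops over the i, p, j indices — no matrix algebra — so they
stay independent of the vectorized implementation they check.
"""

import numpy as np
import pytest

from blocknmf.model import DEFAULT_EPSILON


def oracle_update_H(V, W, H, epsilon=DEFAULT_EPSILON):
    """H_pj <- H_pj * (sum_i W_ip V_ij / (WH)_ij) / (sum_r W_rp), by loops."""
    n, k = W.shape
    m = H.shape[1]
    WH = [[sum(W[i][p] * H[p][j] for p in range(k)) for j in range(m)] for i in range(n)]
    out = np.zeros((k, m))
    for p in range(k):
        den = sum(W[r][p] for r in range(n)) + epsilon
        for j in range(m):
            num = sum(W[i][p] * V[i][j] / (WH[i][j] + epsilon) for i in range(n))
            out[p][j] = H[p][j] * num / den
    return out


def oracle_update_W(V, W, H, epsilon=DEFAULT_EPSILON):
    """W_ip <- W_ip * (sum_j V_ij H_pj / (WH)_ij) / (sum_t H_pt), by loops."""
    n, k = W.shape
    m = H.shape[1]
    WH = [[sum(W[i][p] * H[p][j] for p in range(k)) for j in range(m)] for i in range(n)]
    out = np.zeros((n, k))
    for p in range(k):
        den = sum(H[p][t] for t in range(m)) + epsilon
        for i in range(n):
            num = sum(V[i][j] * H[p][j] / (WH[i][j] + epsilon) for j in range(m))
            out[i][p] = W[i][p] * num / den
    return out


def oracle_kl(V, W, H):
    """D(V || WH) by elementwise scalar loops, 0*log(0) treated as 0."""
    import math

    n, k = W.shape
    m = H.shape[1]
    total = 0.0
    for i in range(n):
        for j in range(m):
            wh = sum(W[i][p] * H[p][j] for p in range(k))
            v = V[i][j]
            if v > 0:
                if wh == 0:
                    return float("inf")
                total += v * math.log(v / wh) - v + wh
            else:
                total += wh
    return total


def random_instance(rng, max_n=10, max_m=10, max_k=4):
    """A random strictly positive (V, W, H) triple with conformable shapes."""
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(2, max_m + 1))
    k = int(rng.integers(1, min(max_k, n, m) + 1))
    V = rng.random((n, m)) + 0.05
    W = rng.random((n, k)) + 0.05
    H = rng.random((k, m)) + 0.05
    return V, W, H


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def worked():
    from blocknmf.synthetic import make_worked_instances

    return make_worked_instances()
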