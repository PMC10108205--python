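"""Independent oracles used by the test suite.

These deliberately avoid the package's own forward recursion and
uniformization code paths: transition kernels come from scipy's expm and
likelihoods from explicit hidden-path enumeration.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm

from moranselect.moran_core import build_rate_matrix, emission_kernel


def series_expm(Q: np.ndarray, dt: float, terms: int = 80) -> np.ndarray:
    """Brute-force truncated Taylor series of exp(Q dt)."""
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, terms):
        term = term @ (Q * dt) / k
        out = out + term
    return out


def brute_force_locus_loglik(counts, sigma: float, N: int) -> float:
    """Log likelihood by summation over every hidden-state path."""
    model = build_rate_matrix(N, sigma)
    g = counts.generations
    T = len(g)
    total = 0.0
    for r in range(counts.n_replicates):
        c, C = counts.counts[r], counts.coverage[r]
        Ps = [expm(model.Q * (g[t] - g[t - 1])) for t in range(1, T)]
        emits = [emission_kernel(int(c[t]), int(C[t]), N) for t in range(T)]
        acc = 0.0
        for path in itertools.product(range(N + 1), repeat=T):
            p = emits[0][path[0]] / (N + 1)
            for t in range(1, T):
                p *= Ps[t - 1][path[t - 1], path[t]] * emits[t][path[t]]
            acc += p
        total += math.log(acc)
    return total


def moran_fixation_prob(N: int, i: int, sigma: float) -> float:
    """Birth-death absorption closed form (1 - g^i) / (1 - g^N), g = 1/(1+sigma)."""
    if sigma == 0.0:
        return i / N
    g = 1.0 / (1.0 + sigma)
    return (1.0 - g**i) / (1.0 - g**N)


def lstsq_gamma_fit(sigma_points, log_post):
    """Generic linear least squares on the design [1, log x, -x], x = 1+sigma."""
    x = 1.0 + np.asarray(sigma_points, dtype=float)
    A = np.column_stack([np.ones_like(x), np.log(x), -x])
    coef, *_ = np.linalg.lstsq(A, np.asarray(log_post, dtype=float), rcond=None)
    c, a, b = coef
    return a + 1.0, b, c  # alpha, beta, c
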