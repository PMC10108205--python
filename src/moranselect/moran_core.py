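"""Continuous-time Moran model core.

State space is the allele copy number n = 0..N.  A randomly chosen
individual reproduces while another is drawn to die, so per Moran event the
chain moves n -> n-1 at rate (n/N)((N-n)/N) and n -> n+1 at rate
(n/N)((N-n)/N)(1+sigma), where 1+sigma is the fitness of the focal allele.
One generation corresponds to N Moran events, so the per-generation
generator is N times the event-scale rates.  Boundaries 0 and N are
absorbing (no mutation).

Observed pool-seq counts c out of depth C are binomial (optionally
beta-binomial) draws given the latent frequency n/N; trajectory likelihoods
marginalise the hidden chain with a forward recursion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .sync_io import LocusCounts

__all__ = [
    "EmissionModel",
    "MoranModel",
    "build_rate_matrix",
    "transition_matrix",
    "emission_kernel",
    "state_posterior",
    "replicate_loglik",
    "locus_loglik",
    "clear_transition_cache",
]

#: truncation tail mass for the uniformization series
_UNIF_TAIL = 1e-12


@dataclass(frozen=True)
class EmissionModel:
    """Pool-seq read sampling model: binomial or beta-binomial.

    ``rho`` is the beta-binomial overdispersion in [0, 1); rho = 0 reduces
    to the pure binomial.
    """

    kind: str = "binomial"
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("binomial", "beta-binomial"):
            raise ValueError(f"unknown emission kind {self.kind!r}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.kind == "binomial" and self.rho != 0.0:
            raise ValueError("binomial emission cannot carry overdispersion")


@dataclass(frozen=True)
class MoranModel:
    """Population size N, selection coefficient sigma and generator Q.

    ``Q`` is the per-generation rate matrix over states 0..N: tridiagonal,
    rows summing to zero, rows 0 and N identically zero (absorption).
    """

    N: int
    sigma: float
    Q: np.ndarray

    @property
    def n_states(self) -> int:
        return self.N + 1


def build_rate_matrix(N: int, sigma: float) -> MoranModel:
    """Per-generation Moran generator for fitness 1 + sigma.

    Event-scale rates are down = (n/N)((N-n)/N) and up = down * (1+sigma);
    the per-generation Q multiplies both by N (one generation = N events).
    """
    if N < 1:
        raise ValueError(f"N must be a positive integer, got {N}")
    if sigma <= -1.0:
        raise ValueError(f"sigma must exceed -1 (fitness must be positive), got {sigma}")
    n = np.arange(N + 1, dtype=float)
    event = (n / N) * ((N - n) / N)
    down = N * event
    up = N * event * (1.0 + sigma)
    Q = np.zeros((N + 1, N + 1))
    idx = np.arange(1, N)  # boundary rows stay zero
    Q[idx, idx - 1] = down[idx]
    Q[idx, idx + 1] = up[idx]
    Q[idx, idx] = -(down[idx] + up[idx])
    Q.flags.writeable = False
    return MoranModel(N=N, sigma=float(sigma), Q=Q)


def _uniformized_expm(Q: np.ndarray, dt: float) -> np.ndarray:
    """exp(Q dt) by uniformization with scaling and squaring.

    The Poisson-weighted power series is truncated once the accumulated
    Poisson mass exceeds 1 - _UNIF_TAIL; dt is halved until lambda*dt <= 1
    and the result squared back, which keeps every term non-negative.
    """
    m = Q.shape[0]
    lam = float(-Q.diagonal().min())
    if lam * dt == 0.0:
        return np.eye(m)
    n_sq = max(0, int(np.ceil(np.log2(lam * dt))))
    tau = dt / 2**n_sq
    M = np.eye(m) + Q / lam
    w = np.exp(-lam * tau)
    term = np.eye(m)
    P = w * term
    cum = w
    k = 0
    while 1.0 - cum > _UNIF_TAIL:
        k += 1
        term = term @ M
        w *= lam * tau / k
        P += w * term
        cum += w
    for _ in range(n_sq):
        P = P @ P
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


@lru_cache(maxsize=64)
def _transition_matrix_cached(N: int, sigma_key: float, dt_key: float) -> np.ndarray:
    P = _uniformized_expm(build_rate_matrix(N, sigma_key).Q, dt_key)
    P.flags.writeable = False
    return P


def clear_transition_cache() -> None:
    _transition_matrix_cached.cache_clear()


def transition_matrix(model: MoranModel, dt: float) -> np.ndarray:
    """Stochastic matrix exp(Q dt) over dt generations (dt >= 0, real).

    Cached on (N, sigma, dt); the returned array is read-only.
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    return _transition_matrix_cached(model.N, round(float(model.sigma), 12), round(float(dt), 12))


def emission_kernel(c: int, C: int, N: int, emission: EmissionModel = EmissionModel()) -> np.ndarray:
    """P(c | C, n) for every hidden state n = 0..N (unnormalised in n).

    C = 0 yields the all-ones vector (no information).  Beta-binomial uses
    mean n/N and overdispersion rho; boundary states fall back to the
    degenerate binomial kernel.
    """
    if not 0 <= c <= C:
        raise ValueError(f"need 0 <= c <= C, got c={c}, C={C}")
    if C == 0:
        return np.ones(N + 1)
    p = np.arange(N + 1) / N
    if emission.rho == 0.0:
        return stats.binom.pmf(c, C, p)
    rho = emission.rho
    k = np.empty(N + 1)
    a = p[1:-1] * (1.0 - rho) / rho
    b = (1.0 - p[1:-1]) * (1.0 - rho) / rho
    k[1:-1] = stats.betabinom.pmf(c, C, a, b)
    k[0] = 1.0 if c == 0 else 0.0
    k[-1] = 1.0 if c == C else 0.0
    return k


def state_posterior(
    c: int, C: int, N: int, emission: EmissionModel = EmissionModel()
) -> np.ndarray:
    """Posterior over Moran states given one count, uniform state prior.

    Normalised binomial (or beta-binomial) kernel over n = 0..N; C = 0
    returns the uniform distribution.
    """
    k = emission_kernel(c, C, N, emission)
    total = k.sum()
    if total <= 0.0:
        raise ValueError("emission kernel vanished for every state")
    return k / total


def _forward_loglik(
    c_row: np.ndarray,
    C_row: np.ndarray,
    generations: np.ndarray,
    model: MoranModel,
    emission: EmissionModel,
) -> float:
    """HMM forward pass: log marginal of one replicate's count series.

    Initial weight is uniform over states times the first emission, i.e.
    the single-time-point marginal; each step propagates by exp(Q dt) and
    multiplies the next emission, rescaling to avoid underflow.  A locus
    with a single uncovered time point therefore scores log 1 = 0.
    """
    N = model.N
    f = emission_kernel(int(c_row[0]), int(C_row[0]), N, emission) / (N + 1)
    loglik = 0.0
    s = f.sum()
    if s <= 0.0:
        return -np.inf
    loglik += np.log(s)
    f = f / s
    for t in range(1, len(generations)):
        P = transition_matrix(model, generations[t] - generations[t - 1])
        f = f @ P
        f = f * emission_kernel(int(c_row[t]), int(C_row[t]), N, emission)
        s = f.sum()
        if s <= 0.0:
            return -np.inf
        loglik += np.log(s)
        f = f / s
    return float(loglik)


def _smoothed_loglik(
    c_row: np.ndarray,
    C_row: np.ndarray,
    generations: np.ndarray,
    model: MoranModel,
    emission: EmissionModel,
) -> float:
    # plug-in alternative: smooth each time point independently, then score
    # consecutive state-posterior pairs under the transition kernel
    N = model.N
    posts = [state_posterior(int(c), int(C), N, emission) for c, C in zip(c_row, C_row)]
    loglik = 0.0
    for t in range(1, len(generations)):
        P = transition_matrix(model, generations[t] - generations[t - 1])
        step = float(posts[t - 1] @ P @ posts[t])
        if step <= 0.0:
            return -np.inf
        loglik += np.log(step)
    return loglik


def replicate_loglik(
    counts: LocusCounts,
    r: int,
    model: MoranModel,
    emission: EmissionModel = EmissionModel(),
    method: str = "hmm",
) -> float:
    """Log marginal probability of replicate ``r``'s observed counts.

    ``method="hmm"`` (default) marginalises the hidden Moran chain jointly;
    ``method="smoothed"`` scores independently smoothed state posteriors.
    """
    if counts.n_times < 1:
        raise ValueError("need at least one time point")
    fn = {"hmm": _forward_loglik, "smoothed": _smoothed_loglik}.get(method)
    if fn is None:
        raise ValueError(f"unknown likelihood method {method!r}")
    return fn(counts.counts[r], counts.coverage[r], counts.generations, model, emission)


def locus_loglik(
    counts: LocusCounts,
    sigma: float,
    N: int,
    emission: EmissionModel = EmissionModel(),
    method: str = "hmm",
) -> float:
    """Joint log likelihood over independent replicates (their log sum)."""
    if counts.n_replicates < 1:
        raise ValueError("need at least one replicate")
    model = build_rate_matrix(N, sigma)
    return float(
        sum(replicate_loglik(counts, r, model, emission, method) for r in range(counts.n_replicates))
    )
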