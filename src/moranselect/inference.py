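"""Posterior inference of the selection coefficient for a single locus.

The unnormalised log posterior of sigma is evaluated on a small grid and
fitted by least squares to a gamma log-density surface

    log p(x) = c + (alpha - 1) log x - beta x,

where x = 1 + sigma is the fitness of the focal allele.  Fitting in fitness
space gives the gamma support x > 0, i.e. sigma in (-1, inf), and makes the
neutral boundary x = 1 a natural two-sided split for the Bayes factor: the
reported log BF is the log posterior odds of sigma > 0 versus sigma < 0,
so posterior mass 0.99 above neutrality yields log(0.99/0.01) ~= 4.6.

The closed-form least-squares estimators are expressed in the moment sums
s1..s8 of the grid (x, log x and the log-posterior values); they solve the
3x3 normal equations of the design [1, log x, -x] exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from . import prefilter
from .moran_core import EmissionModel, locus_loglik
from .sync_io import LocusCounts, LocusResult

__all__ = [
    "SigmaGrid",
    "GammaPrior",
    "GammaPosterior",
    "DEFAULT_COARSE_RANGE",
    "DEFAULT_COARSE_POINTS",
    "choose_grid",
    "log_posterior_at",
    "fit_gamma_surface",
    "summarize",
    "analyse_locus",
]

DEFAULT_COARSE_RANGE: Tuple[float, float] = (-0.5, 0.5)
DEFAULT_COARSE_POINTS = 21
#: number of final grid points fitted to the gamma surface
N_FINAL_POINTS = 5
#: log-BF saturation bound (|log| of the largest finite double ratio)
LOG_BF_CLAMP = 709.0


@dataclass
class SigmaGrid:
    """Strictly increasing sigma values with unnormalised log posteriors."""

    points: np.ndarray
    log_post: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size < 3:
            raise ValueError("grid needs at least 3 points")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if np.any(self.points <= -1.0):
            raise ValueError("all sigma values must exceed -1")
        if self.log_post is not None:
            self.log_post = np.asarray(self.log_post, dtype=float)
            if self.log_post.shape != self.points.shape:
                raise ValueError("points and log_post lengths differ")


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(a0, b0) prior on the fitness x = 1 + sigma (shape, rate)."""

    a0: float = 0.001
    b0: float = 0.001

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.b0 <= 0:
            raise ValueError("prior shape and rate must be positive")

    def logpdf(self, sigma: float) -> float:
        return float(stats.gamma.logpdf(1.0 + sigma, self.a0, scale=1.0 / self.b0))


@dataclass
class GammaPosterior:
    """Fitted gamma surface and derived posterior summaries.

    ``alpha``/``beta`` parameterise the gamma over fitness x = 1 + sigma,
    so mean_sigma = alpha/beta - 1 and var_sigma = alpha/beta**2.
    """

    alpha: float
    beta: float
    c: float
    mean_sigma: Optional[float] = None
    var_sigma: Optional[float] = None
    log_bf: Optional[float] = None
    saturated: bool = False

    @property
    def degenerate(self) -> bool:
        return not (self.alpha > 0 and self.beta > 0)


def choose_grid(
    counts: LocusCounts,
    N: int,
    emission: EmissionModel = EmissionModel(),
    coarse_range: Tuple[float, float] = DEFAULT_COARSE_RANGE,
    coarse_points: int = DEFAULT_COARSE_POINTS,
    method: str = "hmm",
) -> SigmaGrid:
    """Pick the five sigma values used for the gamma-surface fit.

    A coarse likelihood scan over ``coarse_range`` locates the maximum;
    the final grid is the five coarse nodes centred on the argmax (+-2
    coarse steps), shifted inward when the argmax sits near a boundary.
    A flat scan falls back to the symmetric default grid around 0.
    """
    lo, hi = coarse_range
    if not (lo > -1.0 and hi > lo and coarse_points >= N_FINAL_POINTS):
        raise ValueError("invalid coarse scan settings")
    coarse = np.linspace(lo, hi, coarse_points)
    ll = np.array([locus_loglik(counts, s, N, emission, method) for s in coarse])
    if not np.all(np.isfinite(ll)) or np.ptp(ll) < 1e-9:
        # flat (or broken) likelihood: symmetric default grid around 0
        step = (hi - lo) / (coarse_points - 1)
        pts = np.arange(-(N_FINAL_POINTS // 2), N_FINAL_POINTS // 2 + 1) * step
        if pts[0] <= -1.0:
            pts = pts - pts[0] - 1.0 + step  # keep sigma > -1
        return SigmaGrid(points=pts)
    start = int(np.clip(np.argmax(ll) - N_FINAL_POINTS // 2, 0, coarse_points - N_FINAL_POINTS))
    return SigmaGrid(points=coarse[start : start + N_FINAL_POINTS])


def log_posterior_at(
    sigma: float,
    counts: LocusCounts,
    N: int,
    emission: EmissionModel = EmissionModel(),
    prior: GammaPrior = GammaPrior(),
    method: str = "hmm",
) -> float:
    """Unnormalised log posterior: log likelihood + log gamma prior."""
    if sigma <= -1.0:
        raise ValueError(f"sigma must exceed -1, got {sigma}")
    return locus_loglik(counts, sigma, N, emission, method) + prior.logpdf(sigma)


def fit_gamma_surface(grid: SigmaGrid) -> GammaPosterior:
    """Closed-form least-squares fit of the gamma log-density surface.

    Minimises sum_i (y_i - [c + (alpha-1) log x_i - beta x_i])^2 over the
    grid x_i = 1 + sigma_i with y_i the log posterior values, via the
    moment sums s1..s8 (Cramer solution of the normal equations; evaluated
    in extended precision since the x_i cluster near 1).  A non-positive
    alpha or beta marks the fit degenerate; the caller decides how to
    report it.
    """
    if grid.log_post is None:
        raise ValueError("grid carries no log-posterior values")
    x = np.asarray(1.0 + grid.points, dtype=np.longdouble)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct grid points")
    if np.any(x <= 0):
        raise ValueError("fitted variable must be strictly positive")
    shift = float(np.max(grid.log_post))
    y = np.asarray(grid.log_post, dtype=np.longdouble) - shift
    L = np.log(x)

    s1 = x.mean()
    s2 = y.mean()
    s3 = (x * y).mean()
    s4 = L.mean()
    s5 = (x * L).mean()
    s6 = (y * L).mean()
    s7 = (L * L).mean()
    s8 = (x * x).mean()

    # normal equations  [[1, s4, -s1], [s4, s7, -s5], [s1, s5, -s8]] (c, a, b)
    # = (s2, s6, s3) with a = alpha - 1, b = beta
    det = s7 * s1 * s1 - 2.0 * s1 * s4 * s5 + s5 * s5 + s4 * s4 * s8 - s7 * s8
    if det == 0:
        raise ValueError("singular design: grid points too degenerate to fit")
    det_c = (
        s2 * (s7 * (-s8) + s5 * s5)
        - s4 * (s6 * (-s8) + s5 * s3)
        + (-s1) * (s6 * s5 - s7 * s3)
    )
    det_a = (
        1.0 * (s6 * (-s8) + s5 * s3)
        - s2 * (s4 * (-s8) + s5 * s1)
        + (-s1) * (s4 * s3 - s6 * s1)
    )
    det_b = (
        1.0 * (s7 * s3 - s5 * s6)
        - s4 * (s4 * s3 - s1 * s6)
        + s2 * (s4 * s5 - s1 * s7)
    )
    c_hat = float(det_c / det) + shift
    alpha_hat = float(det_a / det) + 1.0
    beta_hat = float(det_b / det)
    return GammaPosterior(alpha=alpha_hat, beta=beta_hat, c=c_hat)


def summarize(alpha: float, beta: float) -> Tuple[float, float, float, bool]:
    """Posterior mean/variance of sigma and the two-sided log Bayes factor.

    With the gamma fitted over fitness x = 1 + sigma: mean_sigma =
    alpha/beta - 1, var_sigma = alpha/beta**2, and log BF =
    log[(1 - F(1)) / F(1)] with F the fitted gamma CDF at the neutral
    fitness x = 1.  Saturated odds are clamped to +-709 and flagged.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("summaries require a non-degenerate fit (alpha, beta > 0)")
    mean_sigma = alpha / beta - 1.0
    var_sigma = alpha / beta**2
    dist = stats.gamma(alpha, scale=1.0 / beta)
    log_cdf, log_sf = dist.logcdf(1.0), dist.logsf(1.0)
    saturated = False
    if not np.isfinite(log_cdf) or not np.isfinite(log_sf):
        log_bf = LOG_BF_CLAMP if not np.isfinite(log_cdf) else -LOG_BF_CLAMP
        saturated = True
    else:
        log_bf = float(log_sf - log_cdf)
        if abs(log_bf) > LOG_BF_CLAMP:
            log_bf = math.copysign(LOG_BF_CLAMP, log_bf)
            saturated = True
    return mean_sigma, var_sigma, log_bf, saturated


def analyse_locus(
    counts: LocusCounts,
    N: int,
    emission: EmissionModel = EmissionModel(),
    prior: GammaPrior = GammaPrior(),
    filter_threshold: float = prefilter.DEFAULT_THRESHOLD,
    filter_mode: str = "pooled",
    coarse_range: Tuple[float, float] = DEFAULT_COARSE_RANGE,
    coarse_points: int = DEFAULT_COARSE_POINTS,
    method: str = "hmm",
) -> LocusResult:
    """Full single-locus pipeline: filter, grid, fit, summarise.

    Filtered loci yield a flagged result with no statistics; degenerate
    gamma fits are reported (alpha/beta kept, summaries withheld) rather
    than raised.
    """
    verdict = prefilter.apply_filter(counts, threshold=filter_threshold, mode=filter_mode)
    if not verdict.passed:
        return LocusResult(chrom=counts.chrom, pos=counts.pos, filtered=True)
    grid = choose_grid(counts, N, emission, coarse_range, coarse_points, method)
    grid.log_post = np.array(
        [log_posterior_at(s, counts, N, emission, prior, method) for s in grid.points]
    )
    gp = fit_gamma_surface(grid)
    if gp.degenerate:
        return LocusResult(
            chrom=counts.chrom,
            pos=counts.pos,
            alpha=gp.alpha,
            beta=gp.beta,
            degenerate=True,
        )
    mean_sigma, _var, log_bf, _sat = summarize(gp.alpha, gp.beta)
    return LocusResult(
        chrom=counts.chrom,
        pos=counts.pos,
        mean_sigma=mean_sigma,
        log_bf=log_bf,
        alpha=gp.alpha,
        beta=gp.beta,
    )
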