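"""Moran trajectory and pool-seq simulator.

Latent allele-count trajectories are generated by exact event-driven
(Gillespie) simulation of the continuous-time Moran chain whose
per-generation generator matches the inference model, so recovery tests
carry no model mismatch.  Pool-seq counts are binomial (or beta-binomial)
draws at each requested generation.  Scenario presets mirror the simulated
experimental grid: population sizes 100/300/1000, starting frequencies
0.01-0.5, scaled selection 0/1/10, coverages 20/60/100, 2/5/10 replicates
and six named time schemes (fractions of Ne generations).

All randomness flows through numpy SeedSequence spawning: locus, replicate
and read-sampling streams are independent, so regenerating a panel with a
different coverage keeps the latent trajectories identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .moran_core import EmissionModel
from .sync_io import LocusCounts, SyncRecord, write_sync

__all__ = [
    "TIME_SCHEMES",
    "SimScenario",
    "base_scenario",
    "simulate_trajectory",
    "simulate_to_absorption",
    "sample_pool_seq",
    "simulate_locus",
    "generate_panel",
]

#: named sampling schemes, in fractions of Ne generations
TIME_SCHEMES = {
    "TS1": (0.0, 0.2),
    "TS2": (0.0, 0.05, 0.10, 0.15, 0.20),
    "TS3": (0.0, 0.04, 0.08, 0.12, 0.20),
    "TS4": (0.0, 0.08, 0.12, 0.16, 0.20),
    "TS5": (0.0, 0.1, 0.2, 0.3, 0.4),
    "TS6": (0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12, 0.14, 0.16, 0.18, 0.20),
}


@dataclass(frozen=True)
class SimScenario:
    """Population and experimental parameters for one simulated locus."""

    Ne: int = 300
    p0: float = 0.5
    sigma: float = 0.0
    time_points: Sequence[float] = ()  # generations, increasing from 0
    replicates: int = 5
    coverage: int = 60
    emission: EmissionModel = field(default_factory=EmissionModel)
    seed: int = 0
    coverage_model: str = "fixed"  # or "poisson"

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be positive")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        if self.sigma <= -1.0:
            raise ValueError("sigma must exceed -1")
        tp = tuple(float(t) for t in self.time_points)
        if not tp or tp[0] != 0.0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must increase strictly from 0")
        object.__setattr__(self, "time_points", tp)
        if self.replicates < 1 or self.coverage < 1:
            raise ValueError("replicates and coverage must be positive")
        if self.coverage_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown coverage model {self.coverage_model!r}")

    @property
    def n0(self) -> int:
        """Initial copy number: round(p0 * Ne)."""
        return int(round(self.p0 * self.Ne))


def base_scenario(p0: float = 0.5, scaled_sigma: float = 0.0, Ne: int = 300, **kw) -> SimScenario:
    """The reference design: 5 replicates, 5 uniform time points over
    0.2*Ne generations, 60x coverage.  ``scaled_sigma`` is Ne*sigma."""
    times = tuple(f * Ne for f in TIME_SCHEMES["TS2"])
    return SimScenario(
        Ne=Ne, p0=p0, sigma=scaled_sigma / Ne, time_points=times, **kw
    )


def simulate_trajectory(scn: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Exact Gillespie path of one replicate, recorded at the requested
    generations.  Absorbed states (0 or Ne) stay absorbed."""
    N, sigma = scn.Ne, scn.sigma
    up_frac = (1.0 + sigma) / (2.0 + sigma)
    n = scn.n0
    t = 0.0
    out = np.empty(len(scn.time_points), dtype=np.int64)
    for i, target in enumerate(scn.time_points):
        while 0 < n < N:
            total_rate = (2.0 + sigma) * n * (N - n) / N  # per generation
            t_next = t + rng.exponential(1.0 / total_rate)
            if t_next > target:
                break  # memoryless: discard the residual waiting time
            t = t_next
            n += 1 if rng.random() < up_frac else -1
        t = max(t, target)
        out[i] = n
    return out


def simulate_to_absorption(
    N: int, n0: int, sigma: float, n_runs: int, rng: np.random.Generator
) -> float:
    """Fraction of runs fixing (absorbing at N) from n0 copies.

    Uses the embedded jump chain of the Moran process - a +-1 walk stepping
    up with probability (1+sigma)/(2+sigma) - which has exactly the same
    absorption law as the continuous-time chain, vectorised over runs.
    Expected closed form: (1 - g^n0) / (1 - g^N) with g = 1/(1+sigma).
    """
    if not 0 <= n0 <= N:
        raise ValueError("n0 must lie in [0, N]")
    up = (1.0 + sigma) / (2.0 + sigma)
    state = np.full(n_runs, n0, dtype=np.int64)
    active = (state > 0) & (state < N)
    while active.any():
        steps = np.where(rng.random(int(active.sum())) < up, 1, -1)
        state[active] += steps
        active = (state > 0) & (state < N)
    return float(np.mean(state == N))


def sample_pool_seq(
    traj: np.ndarray, scn: SimScenario, rng: np.random.Generator
) -> tuple:
    """Pool-seq counts (c, C) for one replicate trajectory."""
    T = len(scn.time_points)
    if scn.coverage_model == "poisson":
        C = rng.poisson(scn.coverage, size=T)
    else:
        C = np.full(T, scn.coverage, dtype=np.int64)
    p = traj / scn.Ne
    if scn.emission.rho > 0.0:
        rho = scn.emission.rho
        c = np.empty(T, dtype=np.int64)
        for t in range(T):
            if p[t] in (0.0, 1.0) or C[t] == 0:
                c[t] = rng.binomial(C[t], p[t])
            else:
                a = p[t] * (1.0 - rho) / rho
                b = (1.0 - p[t]) * (1.0 - rho) / rho
                c[t] = rng.binomial(C[t], rng.beta(a, b))
    else:
        c = rng.binomial(C, p)
    return np.asarray(c, dtype=np.int64), np.asarray(C, dtype=np.int64)


def _locus_streams(seed: int, locus: int, replicates: int):
    """Independent (trajectory, sequencing) generators per replicate.

    Trajectory streams never depend on coverage or emission settings, so
    re-sampling reads under a different depth reuses identical paths.
    """
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(locus,))
    traj_ss, seq_ss = ss.spawn(2)
    traj = [np.random.Generator(np.random.PCG64(s)) for s in traj_ss.spawn(replicates)]
    seq = [np.random.Generator(np.random.PCG64(s)) for s in seq_ss.spawn(replicates)]
    return traj, seq


def simulate_locus(scn: SimScenario, locus: int = 0) -> tuple:
    """Simulate one locus: (trajectories (R, T), LocusCounts)."""
    traj_rngs, seq_rngs = _locus_streams(scn.seed, locus, scn.replicates)
    trajs = np.stack([simulate_trajectory(scn, rng) for rng in traj_rngs])
    counts = np.empty_like(trajs)
    cover = np.empty_like(trajs)
    for r in range(scn.replicates):
        counts[r], cover[r] = sample_pool_seq(trajs[r], scn, seq_rngs[r])
    lc = LocusCounts(
        chrom="sim",
        pos=locus + 1,
        counts=counts,
        coverage=cover,
        generations=np.asarray(scn.time_points),
    )
    return trajs, lc


def _to_sync_record(lc: LocusCounts) -> SyncRecord:
    # focal allele written as T, reference as A; time-major column blocks
    R, T = lc.counts.shape
    sextets = []
    for t in range(T):
        for r in range(R):
            c = int(lc.counts[r, t])
            ref = int(lc.coverage[r, t] - c)
            sextets.append((ref, c, 0, 0, 0, 0))
    return SyncRecord(chrom=lc.chrom, pos=lc.pos, ref="A", samples=tuple(sextets))


def generate_panel(
    scenarios: Union[SimScenario, Sequence[SimScenario]],
    n_loci: int,
    sync_path=None,
    truth_path=None,
    seed: Optional[int] = None,
):
    """Simulate a panel of independent loci; optionally write sync + truth.

    ``scenarios`` may be a single scenario or a sequence cycled over loci
    (all must share replicate count and time points).  The output is fully
    determined by ``seed`` (default: the first scenario's seed).  Returns
    ``(counts_list, truth_rows)`` where each truth row records the locus
    coordinates, p0, sigma and per-replicate fixed/lost tallies at the last
    sampled generation.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be positive")
    scns = [scenarios] if isinstance(scenarios, SimScenario) else list(scenarios)
    if seed is not None:
        scns = [replace(s, seed=seed) for s in scns]
    if len({(s.replicates, s.time_points) for s in scns}) != 1:
        raise ValueError("all scenarios in a panel must share layout")

    counts_list, truth = [], []
    for i in range(n_loci):
        scn = scns[i % len(scns)]
        trajs, lc = simulate_locus(scn, locus=i)
        counts_list.append(lc)
        final = trajs[:, -1]
        truth.append(
            {
                "chrom": lc.chrom,
                "pos": lc.pos,
                "p0": scn.p0,
                "sigma": scn.sigma,
                "scaled_sigma": scn.sigma * scn.Ne,
                "n_fixed": int(np.sum(final == scn.Ne)),
                "n_lost": int(np.sum(final == 0)),
            }
        )
    if sync_path is not None:
        write_sync((_to_sync_record(lc) for lc in counts_list), sync_path)
    if truth_path is not None:
        cols = ("chrom", "pos", "p0", "sigma", "scaled_sigma", "n_fixed", "n_lost")
        with open(truth_path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in truth:
                fh.write(
                    "\t".join(
                        format(row[k], ".6g") if isinstance(row[k], float) else str(row[k])
                        for k in cols
                    )
                    + "\n"
                )
    return counts_list, truth
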