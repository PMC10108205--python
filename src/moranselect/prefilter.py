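"""Allele-frequency variance filter applied before inference.

Trajectories whose observed frequencies barely move are statistically
uninformative and tend to produce inflated estimates and Bayes factors;
they are flagged and skipped (but kept in the output for bookkeeping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sync_io import LocusCounts

__all__ = ["FilterVerdict", "frequency_variance", "apply_filter", "DEFAULT_THRESHOLD"]

DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class FilterVerdict:
    variance: float  # NaN when undefined (fewer than 2 covered samples)
    passed: bool


def frequency_variance(counts: LocusCounts, mode: str = "pooled") -> float:
    """Population variance of observed frequencies c/C, pooled over all
    replicates and time points with non-zero coverage.

    ``mode="increments"`` instead pools the per-step frequency differences
    within each replicate (consecutive covered time points).  Returns NaN
    when fewer than two values are available.
    """
    freqs = counts.frequencies()
    if mode == "pooled":
        vals = freqs[~np.isnan(freqs)]
    elif mode == "increments":
        incs = []
        for r in range(counts.n_replicates):
            row = freqs[r][~np.isnan(freqs[r])]
            if row.size >= 2:
                incs.append(np.diff(row))
        vals = np.concatenate(incs) if incs else np.empty(0)
    else:
        raise ValueError(f"unknown variance mode {mode!r}")
    if vals.size < 2:
        return math.nan
    return float(np.var(vals))


def apply_filter(
    counts: LocusCounts, threshold: float = DEFAULT_THRESHOLD, mode: str = "pooled"
) -> FilterVerdict:
    """Keep a locus iff its frequency variance is at least ``threshold``.

    The boundary is inclusive on the keep side: variance exactly equal to
    the threshold passes ("lower than" is excluded).  An undefined variance
    fails.
    """
    var = frequency_variance(counts, mode=mode)
    passed = bool(var >= threshold) if not math.isnan(var) else False
    return FilterVerdict(variance=var, passed=passed)
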