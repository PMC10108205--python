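"""Flat key-value run configuration.

The config file uses one ``Key value`` pair per line (comma- or
whitespace-separated values), e.g.::

    Population_size   300
    Prior_parameters  0.001, 0.001
    Generations       0, 15, 30, 45, 60
    Replicates        5
    Layout            time_major
    Filter_threshold  0.01
    Emission          binomial
    Rho               0.0
    Seed              1

``Population_size``, ``Generations`` and ``Replicates`` are required; the
sync format carries no time metadata, so sampling generations must always
be given explicitly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Tuple

from .inference import DEFAULT_COARSE_POINTS, DEFAULT_COARSE_RANGE, GammaPrior
from .moran_core import EmissionModel
from .prefilter import DEFAULT_THRESHOLD
from .sync_io import LAYOUTS

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config_text", "config_hash"]

REQUIRED_KEYS = ("Population_size", "Generations", "Replicates")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass(frozen=True)
class RunConfig:
    population_size: int
    generations: Tuple[float, ...]
    replicates: int
    prior: GammaPrior = field(default_factory=GammaPrior)
    layout: str = "time_major"
    emission: EmissionModel = field(default_factory=EmissionModel)
    filter_threshold: float = DEFAULT_THRESHOLD
    filter_mode: str = "pooled"
    coarse_range: Tuple[float, float] = DEFAULT_COARSE_RANGE
    coarse_points: int = DEFAULT_COARSE_POINTS
    likelihood: str = "hmm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 1:
            raise ConfigError("Population_size must be a positive integer")
        if self.replicates < 1:
            raise ConfigError("Replicates must be a positive integer")
        if len(self.generations) < 1 or any(
            b <= a for a, b in zip(self.generations, self.generations[1:])
        ):
            raise ConfigError("Generations must be strictly increasing")
        if self.layout not in LAYOUTS:
            raise ConfigError(f"Layout must be one of {LAYOUTS}")

    @property
    def n_samples(self) -> int:
        return self.replicates * len(self.generations)


def _values(raw: str) -> list:
    return [tok for tok in raw.replace(",", " ").split() if tok]


def parse_config_text(text: str) -> RunConfig:
    pairs = {}
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ConfigError(f"config line {i}: expected 'Key value', got {line!r}")
        pairs[parts[0]] = parts[1].strip()
    for key in REQUIRED_KEYS:
        if key not in pairs:
            raise ConfigError(f"missing required config key: {key}")

    try:
        prior_vals = _values(pairs.get("Prior_parameters", "0.001 0.001"))
        if len(prior_vals) != 2:
            raise ConfigError("Prior_parameters needs exactly two values (shape, rate)")
        coarse = _values(pairs.get("Sigma_range", "-0.5 0.5"))
        if len(coarse) != 2:
            raise ConfigError("Sigma_range needs exactly two values")
        kind = pairs.get("Emission", "binomial")
        rho = float(pairs.get("Rho", "0"))
        return RunConfig(
            population_size=int(pairs["Population_size"]),
            generations=tuple(float(g) for g in _values(pairs["Generations"])),
            replicates=int(pairs["Replicates"]),
            prior=GammaPrior(a0=float(prior_vals[0]), b0=float(prior_vals[1])),
            layout=pairs.get("Layout", "time_major"),
            emission=EmissionModel(kind=kind, rho=rho),
            filter_threshold=float(pairs.get("Filter_threshold", str(DEFAULT_THRESHOLD))),
            filter_mode=pairs.get("Filter_mode", "pooled"),
            coarse_range=(float(coarse[0]), float(coarse[1])),
            coarse_points=int(pairs.get("Sigma_points", str(DEFAULT_COARSE_POINTS))),
            likelihood=pairs.get("Likelihood", "hmm"),
            seed=int(pairs.get("Seed", "0")),
        )
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"invalid config value: {exc}") from exc


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return parse_config_text(fh.read())


def config_hash(cfg: RunConfig) -> str:
    """Short stable digest of the full configuration, for provenance."""
    return hashlib.md5(repr(cfg).encode()).hexdigest()[:12]
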