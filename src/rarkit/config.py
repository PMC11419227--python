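"""Run configuration for the rarkit pipeline.

All tunables live in one flat-ish dataclass so that a single YAML file (or the
CLI defaults) fully determines a run.  Every analysis entry point accepts an
optional :class:`Config`; ``Config()`` reproduces the published procedure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class ExtendedCosineConfig:
    """Tunables of the sigmoidally transformed cosine fit.

    df_numerator: numerator degrees of freedom of the pseudo-F ratio.  The
        model has p = 5 free parameters, so the standard choice is p - 1 = 4.
    phase_offsets_h: offsets (hours) around the cosinor acrophase used to seed
        the multi-start phase grid.
    beta_starts: initial steepness values for the multi-start grid.
    max_iter: per-start cap on least-squares function evaluations.
    tolerance: convergence tolerance (ftol/xtol) of the least-squares solver.
    """

    df_numerator: int = 4
    phase_offsets_h: tuple[float, ...] = (0.0, -2.0, 2.0, -4.0, 4.0)
    beta_starts: tuple[float, ...] = (1.0, 5.0, 20.0)
    max_iter: int = 150
    tolerance: float = 1e-8


@dataclass
class SleepConfig:
    """Sleep-bout detection rule: a maximal run of epochs with counts at or
    below ``zero_tolerance`` lasting at least ``min_bout_minutes``."""

    min_bout_minutes: float = 4.0
    zero_tolerance: int = 0


@dataclass
class IOConfig:
    """CSV dialect of per-subject epoch files (vendor exports vary)."""

    timestamp_column: str = "timestamp"
    counts_column: str = "activity"


@dataclass
class Config:
    io: IOConfig = field(default_factory=IOConfig)
    sleep: SleepConfig = field(default_factory=SleepConfig)
    extended_cosine: ExtendedCosineConfig = field(default_factory=ExtendedCosineConfig)
    kmeans_replicates: int = 2000
    kmeans_k: int = 3

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, values in raw.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            if isinstance(values, dict):
                for key, val in values.items():
                    if not hasattr(target, key):
                        raise KeyError(f"unknown config key {section}.{key}")
                    setattr(target, key, val)
            else:
                setattr(cfg, section, values)
        return cfg

    def digest(self) -> str:
        """Stable hash of the configuration, for run logging."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
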