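"""Run configuration: schema, defaults, validation, seed derivation.

A single master seed drives the whole pipeline; per-stage seeds are
derived from it with ``numpy.random.SeedSequence`` spawning, so every
randomized operation draws from a named, logged seed and no stage shares
a stream with another.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .curation import CurationConfig
from .errors import ConfigError
from .synthetic import Contamination, Trapezoid

STAGE_NAMES = ("network", "env", "occurrences", "pseudoabsence", "modeling", "context", "importance")


@dataclass
class RunConfig:
    seed: int = 0
    # riverscape
    rows: int = 256
    cols: int = 256
    cell_size_km: float = 0.45
    n_sources: int = 24
    meander: float = 0.55
    # truth envelope: per-variable (lo_zero, lo_high, hi_high, hi_zero)
    envelope: dict = field(
        default_factory=lambda: {
            "hyd": [21.0, 63.0, 147.0, 210.0],
            "sgr": [40.0, 120.0, 270.0, 320.0],
            "bio10": [25.5, 26.9, 28.7, 29.7],
        }
    )
    # occurrences
    n_occurrences: int = 250
    contamination: dict = field(
        default_factory=lambda: {
            "uncertain": 0.05,
            "old_date": 0.05,
            "reservoir": 0.05,
            "off_river": 0.05,
        }
    )
    evidence_fraction: float = 0.3
    # curation
    max_uncertainty_m: float = 1000.0
    min_year: int = 1990
    snap_radius_m: float = 500.0
    max_strahler: int = 4
    # variable selection
    correlation_threshold: float = 0.75
    priority_order: list = field(
        default_factory=lambda: ["hyd", "sgr", "bio10", "bio16", "hft"]
    )
    # modeling
    n_runs: int = 10
    n_trees: int = 500
    train_frac: float = 0.8
    tss_threshold: float = 0.7
    n_shuffles: int = 3
    # priority areas
    probability_threshold: float = 0.9
    min_clump_cells: int = 11
    # context layers
    pa_fraction: float = 0.10
    n_villages: int = 20

    def validate(self) -> "RunConfig":
        checks = [
            (self.rows >= 32 and self.cols >= 32, "grid must be at least 32x32"),
            (self.cell_size_km > 0, "cell_size_km must be positive"),
            (self.n_sources >= 1, "n_sources must be >= 1"),
            (0 <= self.meander <= 1, "meander must be in [0, 1]"),
            (self.n_occurrences >= 1, "n_occurrences must be >= 1"),
            (0 <= self.evidence_fraction <= 1, "evidence_fraction must be in [0, 1]"),
            (self.max_uncertainty_m > 0, "max_uncertainty_m must be positive"),
            (self.snap_radius_m > 0, "snap_radius_m must be positive"),
            (self.max_strahler >= 1, "max_strahler must be >= 1"),
            (0 < self.correlation_threshold <= 1, "correlation_threshold must be in (0, 1]"),
            (self.n_runs >= 1, "n_runs must be >= 1"),
            (self.n_trees >= 1, "n_trees must be >= 1"),
            (0 < self.train_frac < 1, "train_frac must be in (0, 1)"),
            (0 <= self.tss_threshold <= 1, "tss_threshold must be in [0, 1]"),
            (0 <= self.probability_threshold < 1, "probability_threshold must be in [0, 1)"),
            (self.min_clump_cells >= 1, "min_clump_cells must be >= 1"),
            (0 <= self.pa_fraction <= 1, "pa_fraction must be in [0, 1]"),
            (self.n_villages >= 0, "n_villages must be >= 0"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        for frac in self.contamination.values():
            if not 0 <= frac <= 1:
                raise ConfigError("contamination fractions must be in [0, 1]")
        for name, bounds in self.envelope.items():
            if len(bounds) != 4 or not (bounds[0] <= bounds[1] <= bounds[2] <= bounds[3]):
                raise ConfigError(f"envelope for {name} must be 4 non-decreasing values")
        return self

    # -- derived objects ----------------------------------------------------

    def stage_seeds(self) -> dict[str, int]:
        """Named per-stage seeds spawned from the master seed (< 2**31)."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGE_NAMES))
        return {
            name: int(child.generate_state(1)[0] % (2**31 - 1))
            for name, child in zip(STAGE_NAMES, children)
        }

    def trapezoids(self) -> dict[str, Trapezoid]:
        return {name: Trapezoid(*bounds) for name, bounds in self.envelope.items()}

    def contamination_obj(self) -> Contamination:
        return Contamination(**self.contamination)

    def curation_config(self) -> CurationConfig:
        return CurationConfig(
            max_uncertainty_m=self.max_uncertainty_m,
            min_year=self.min_year,
            snap_radius_m=self.snap_radius_m,
            max_strahler=self.max_strahler,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**payload).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
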