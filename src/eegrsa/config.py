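"""Configuration objects for the simulation and the full analysis run.

Defaults mirror the study conditions the package emulates: 33 subjects,
32 entities in a 2x2 design (person/place x famous/familiar, 8 per cell),
a 128-channel montage, and epochs spanning 0-800 ms sampled every 5 ms
(200 Hz).  Windows are half-open ``[start, end)`` in milliseconds
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
import yaml

from .errors import InvalidConfigError


@dataclass
class SimulationConfig:
    """Parameters of the synthetic EEG experiment.

    Parameters
    ----------
    n_subjects : int
        Number of simulated participants.
    n_entities_per_cell : int
        Entities per design cell; the four cells are person/place crossed
        with famous/familiar.
    n_channels : int
        Electrodes on the simulated montage (>= 8).
    time_start_ms, time_end_ms, time_step_ms : float
        Epoch time axis in milliseconds; samples at
        ``arange(start, end, step)``.
    signal_window_ms : (float, float)
        Half-open latency window in which the entity-vector signal is
        planted (boxcar temporal profile).
    vector_dim : int
        Dimensionality of the ground-truth entity vectors (>= 2).
    snr : float
        Ratio of within-window signal standard deviation to noise standard
        deviation.  ``snr = 0`` disables the semantic signal entirely.
    confound_beta : float
        Evoked amplitude added per character of the entity name, scaled by
        a fixed spatial loading.
    seed : int
        Master seed; all generator substreams derive from it.
    """

    n_subjects: int = 33
    n_entities_per_cell: int = 8
    n_channels: int = 128
    time_start_ms: float = 0.0
    time_end_ms: float = 800.0
    time_step_ms: float = 5.0
    signal_window_ms: Tuple[float, float] = (300.0, 500.0)
    vector_dim: int = 16
    snr: float = 1.0
    confound_beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise InvalidConfigError("n_subjects must be >= 1")
        if self.n_entities_per_cell < 1:
            raise InvalidConfigError("n_entities_per_cell must be >= 1")
        if self.n_channels < 8:
            raise InvalidConfigError("n_channels must be >= 8")
        if self.vector_dim < 2:
            raise InvalidConfigError("vector_dim must be >= 2")
        if self.time_step_ms <= 0:
            raise InvalidConfigError("time_step_ms must be > 0")
        if self.time_end_ms <= self.time_start_ms:
            raise InvalidConfigError("time axis must have positive extent")
        w0, w1 = self.signal_window_ms
        if not (self.time_start_ms <= w0 < w1 <= self.time_end_ms):
            raise InvalidConfigError(
                "signal_window_ms must lie within the epoch time axis"
            )
        if self.snr < 0:
            raise InvalidConfigError("snr must be >= 0")

    @property
    def n_entities(self) -> int:
        return 4 * self.n_entities_per_cell

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.time_start_ms, self.time_end_ms, self.time_step_ms)


@dataclass
class RunConfig:
    """End-to-end pipeline settings: simulation, vector provider, encoding
    restriction, searchlight geometry and permutation inference."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    provider: str = "toy-static"
    min_words: int = 20
    restrict: str = "all"
    spatial_radius_mm: float = 30.0
    temporal_radius_ms: float = 50.0
    analysis_window_ms: Tuple[float, float] = (0.0, 800.0)
    neighbor_distance_mm: float = 40.0
    n_permutations: int = 1024
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.validate()

    def validate(self) -> None:
        self.simulation.validate()
        if self.provider not in ("toy-static", "toy-contextual"):
            raise InvalidConfigError(f"unknown provider '{self.provider}'")
        if self.restrict not in ("all", "person", "place", "famous", "familiar"):
            raise InvalidConfigError(f"unknown restriction '{self.restrict}'")
        if self.min_words < 1:
            raise InvalidConfigError("min_words must be >= 1")
        if self.spatial_radius_mm <= 0 or self.temporal_radius_ms <= 0:
            raise InvalidConfigError("searchlight radii must be positive")
        if self.neighbor_distance_mm <= 0:
            raise InvalidConfigError("neighbor_distance_mm must be positive")
        if not (0 < self.alpha < 1):
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if self.n_permutations < 100:
            raise InvalidConfigError("n_permutations must be >= 100")
        a0, a1 = self.analysis_window_ms
        s = self.simulation
        if not (s.time_start_ms <= a0 < a1 <= s.time_end_ms):
            raise InvalidConfigError(
                "analysis_window_ms must lie within the epoch time axis"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["signal_window_ms"] = list(
            d["simulation"]["signal_window_ms"]
        )
        d["analysis_window_ms"] = list(d["analysis_window_ms"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "signal_window_ms" in sim:
            sim["signal_window_ms"] = tuple(sim["signal_window_ms"])
        if "analysis_window_ms" in d:
            d["analysis_window_ms"] = tuple(d["analysis_window_ms"])
        return cls(simulation=SimulationConfig(**sim), **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
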