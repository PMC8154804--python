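"""Run configuration: YAML round-trip, validation and hashing.

A RunConfig fully determines a pipeline run: cohort design, artifact
levels, region table, preprocessing variants, parameter grid and the seed.
Every file product carries the config hash so results are traceable to the
exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .core import SpectralAxis
from .reproducibility import DEFAULT_BETA_GRID, DEFAULT_NS_GRID, GridSpec, SIX_VARIANTS
from .synthetic import ArtifactSpec, CohortSpec

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    seed: int
    region: str = "hippocampus"
    n_subjects: int = 10
    n_measurements: int = 3
    n_on: int = 32
    n_off: int = 32
    n_coils: int = 8
    n_points: int = 2048
    spectral_width_hz: float = 4000.0
    between_subject_cv: float = 0.05
    noise_sd: float = 0.5
    phase_drift_sd: float = 0.05
    frequency_drift_sd: float = 0.5
    eddy_amplitude: float = 1.0
    eddy_time_constant: float = 0.012
    variants: Tuple[str, ...] = ("plain",) + SIX_VARIANTS
    beta_values: Tuple[float, ...] = DEFAULT_BETA_GRID
    ns_values: Tuple[int, ...] = DEFAULT_NS_GRID
    output_dir: str = "gabapipe_out"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        self.variants = tuple(self.variants)
        self.beta_values = tuple(float(b) for b in self.beta_values)
        self.ns_values = tuple(int(n) for n in self.ns_values)
        if self.region not in ("hippocampus", "pcc"):
            raise ValueError(f"unknown region {self.region!r}")

    def axis(self) -> SpectralAxis:
        return SpectralAxis(n_points=self.n_points, dwell_time=1.0 / self.spectral_width_hz)

    def cohort(self) -> CohortSpec:
        return CohortSpec(
            n_subjects=self.n_subjects,
            n_measurements=self.n_measurements,
            n_on=self.n_on,
            n_off=self.n_off,
            n_coils=self.n_coils,
            between_subject_cv=self.between_subject_cv,
            noise_sd=self.noise_sd,
            random_seed=self.seed,
        )

    def artifacts(self) -> ArtifactSpec:
        return ArtifactSpec(
            phase_drift_sd=self.phase_drift_sd,
            frequency_drift_sd=self.frequency_drift_sd,
            eddy_amplitude=self.eddy_amplitude,
            eddy_time_constant=self.eddy_time_constant,
        )

    def grid(self) -> GridSpec:
        return GridSpec(beta_values=self.beta_values, ns_values=self.ns_values)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> Dict:
        d = asdict(self)
        d["variants"] = list(self.variants)
        d["beta_values"] = list(self.beta_values)
        d["ns_values"] = list(self.ns_values)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        if "seed" not in data:
            raise ValueError("config is missing the mandatory 'seed'")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(config_dict: Dict) -> str:
    """Short stable hash of a canonical JSON rendering of the config.

    The output directory is excluded: where results are written does not
    change what was computed.
    """
    d = {k: v for k, v in config_dict.items() if k != "output_dir"}
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
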