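"""Pipeline configuration: schema, YAML round-trip, and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with their documented defaults.

    min_qual: Phred cutoff for a base to contribute to conversion counting.
    k_min: distinct conversions required to call a molecule labeled.
    snv_min_frac / snv_min_cov: SNV blacklist thresholds (apparent conversion
        fraction, minimum coverage).
    strict_low_coverage: additionally mask positions below snv_min_cov.
    tau_bounds_h: admissible half-life range for kinetic fits.
    r2_min: goodness-of-fit cutoff for half-life summaries.
    pi: pseudocount (normalized scale) in the injury-response ratio.
    n_perm: permutations for empirical significance.
    seed: base seed for every stochastic stage.
    """

    min_qual: int = 20
    k_min: int = 1
    snv_min_frac: float = 0.25
    snv_min_cov: int = 10
    strict_low_coverage: bool = False
    tau_bounds_h: tuple[float, float] = (0.5, 48.0)
    r2_min: float = 0.7
    pi: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    tag_cell: str = "CB"
    tag_umi: str = "UB"
    tag_gene: str = "GX"

    def __post_init__(self):
        self.tau_bounds_h = tuple(float(x) for x in self.tau_bounds_h)
        if self.min_qual < 0:
            raise ConfigError("min_qual must be >= 0")
        if self.k_min < 1:
            raise ConfigError("k_min must be >= 1")
        if not 0 < self.snv_min_frac <= 1:
            raise ConfigError("snv_min_frac must be in (0, 1]")
        if self.snv_min_cov < 1:
            raise ConfigError("snv_min_cov must be >= 1")
        if not 0 < self.tau_bounds_h[0] < self.tau_bounds_h[1]:
            raise ConfigError("tau_bounds_h must be increasing and positive")
        if not 0 <= self.r2_min <= 1:
            raise ConfigError("r2_min must be in [0, 1]")
        if self.pi < 0:
            raise ConfigError("pi must be >= 0")
        if self.n_perm < 10:
            raise ConfigError("n_perm must be >= 10")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_bounds_h"] = list(self.tau_bounds_h)
        return d

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
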