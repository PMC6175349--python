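"""Run configuration with lossless YAML round-trip.

A single versioned schema covers every workflow (screening, scans, NEB);
CLI flags override file values.  The seed is mandatory because every
stochastic operation in the toolkit must be reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "ConfigError"]

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    schema_version: int = CONFIG_SCHEMA_VERSION
    # engine
    engine: str = "internal"          # internal | external
    params_file: str | None = None    # optional nonbonded table
    combination_rule: str = "lorentz_berthelot"
    cutoff: float | None = 12.0
    external_command: list[str] = field(default_factory=list)
    # complex search
    n_starts: int = 64
    seed: int = 7
    dedup_rmsd: float = 0.25
    # scan
    scan_step: float = 0.25
    scan_range: tuple[float, float] = (-8.0, 8.0)
    # NEB
    neb_images: int = 11
    neb_spring: float = 1.0
    neb_fmax: float = 1e-3
    neb_max_iterations: int = 1000
    neb_climbing: bool = False
    # thermodynamics / output
    temperature: float = 298.15
    output_dir: str = "."

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.seed = int(self.seed)
        if not (0 <= self.seed < 2 ** 31):
            raise ConfigError("seed must be in [0, 2^31)")
        for name in ("dedup_rmsd", "scan_step", "neb_spring", "neb_fmax",
                     "temperature"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_starts < 1:
            raise ConfigError("n_starts must be >= 1")
        if self.neb_images < 3:
            raise ConfigError("neb_images must be >= 3")
        self.scan_range = tuple(float(v) for v in self.scan_range)
        if self.scan_range[0] >= self.scan_range[1]:
            raise ConfigError("scan_range must satisfy z_min < z_max")
        if self.engine not in ("internal", "external"):
            raise ConfigError(f"unknown engine: {self.engine!r}")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scan_range"] = list(self.scan_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: not a mapping")
        return cls.from_dict(data)

    def make_engine(self, cutoff: object = "__config__"):
        """Engine per config.  ``cutoff`` overrides the configured value;
        the screening workflow passes ``None`` (no truncation) because a
        bimolecular complex is smaller than any sensible cutoff, so the
        complex-formation energy model includes all atom pairs."""
        from .energetics import (ExternalXYZEngine, LJCoulombEngine,
                                 default_params, load_params)
        cut = self.cutoff if cutoff == "__config__" else cutoff
        if self.engine == "external":
            if not self.external_command:
                raise ConfigError("external engine requires external_command")
            return ExternalXYZEngine(list(self.external_command))
        if self.params_file:
            params = load_params(self.params_file, self.combination_rule, cut)
        else:
            params = default_params(cut, self.combination_rule)
        return LJCoulombEngine(params)

    def search_config(self):
        from .chirascreen import SearchConfig
        return SearchConfig(n_starts=self.n_starts, seed=self.seed,
                            dedup_rmsd=self.dedup_rmsd)
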