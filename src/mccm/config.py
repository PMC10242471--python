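"""Analysis and run configuration, serializable to YAML/JSON."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .edm import DEFAULT_THETA_GRID

__all__ = ["AnalysisConfig", "RunConfig"]


@dataclass
class AnalysisConfig:
    """Every tunable of the preprocessing -> EDM -> CCM -> scoring chain.

    Defaults: daily sampling (tau = tp = 1 day), log1p + z-score count
    preprocessing, E searched over 1..10, self-only Theiler exclusion,
    8 geometric library sizes with 20 random draws each, 0.05 convergence
    margin, 0.01 delta-rho nonlinearity margin, signed skill-difference
    score convention.
    """

    transform: str = "log1p"
    standardize: bool = True
    tau: int = 1
    tp: int = 1
    E_min: int = 1
    E_max: int = 10
    theta_grid: tuple = DEFAULT_THETA_GRID
    exclusion_radius: int = 0
    nonlinearity_margin: float = 0.01
    run_nonlinearity: bool = True
    gate_on_nonlinearity: bool = False
    library_sizes: tuple | None = None
    library_size_count: int = 8
    n_samples: int = 20
    sampling: str = "random_without_replacement"
    convergence_margin: float = 0.2
    score_convention: str = "skill_difference"

    def __post_init__(self) -> None:
        self.theta_grid = tuple(float(t) for t in self.theta_grid)
        if self.library_sizes is not None:
            self.library_sizes = tuple(int(s) for s in self.library_sizes)
        if self.score_convention not in ("skill_difference", "dominant_skill"):
            raise ValueError(
                f"unknown score_convention {self.score_convention!r}"
            )
        if self.E_min < 1 or self.E_max < self.E_min:
            raise ValueError("need 1 <= E_min <= E_max")

    @property
    def E_range(self) -> range:
        return range(self.E_min, self.E_max + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_grid"] = list(self.theta_grid)
        if self.library_sizes is not None:
            d["library_sizes"] = list(self.library_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """A full pipeline run: analysis settings plus IO and seeding."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    input: str | None = None
    output_dir: str | None = None
    seed: int = 0
    delimiter: str = ","
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis.to_dict(),
            "input": self.input,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "delimiter": self.delimiter,
            "log_level": self.log_level,
        }

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        analysis = AnalysisConfig.from_dict(d.pop("analysis", {}) or {})
        known = {f.name for f in fields(cls)} - {"analysis"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        return cls(analysis=analysis, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
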