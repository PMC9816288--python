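"""Run configuration for the end-to-end experiment."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import DEFAULT_T_STARS
from .pbif import DEFAULT_WINDOWS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Protocol constants and sizes for a full simulation-and-evaluation run.

    One global ``seed`` fans out deterministically: generation cohort uses
    ``seed``, validation cohort ``seed + 1000``, PBIF fitting ``seed + 2000``
    and phantoms ``seed + 3000`` (all well below 2**31 for small seeds).
    """

    seed: int = 0
    n_generation: int = 16
    n_validation: int = 8
    windows: tuple = DEFAULT_WINDOWS
    t_stars: tuple = DEFAULT_T_STARS
    reference_t_star: float = 35.0
    noise_level: float = 0.2
    cv: float = 0.1
    n_tumors: int = 4
    phantom_dims: tuple = (32, 32, 32)
    scan_minutes: float = 65.0
    output_dir: Path = field(default_factory=lambda: Path("pbifkit_run"))

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        for ta, tb in self.windows:
            if not (0 <= ta < tb <= self.scan_minutes):
                raise ValueError(f"scaling window ({ta}, {tb}) outside [0, {self.scan_minutes}]")
        for t in self.t_stars:
            if not 0 <= t < self.scan_minutes:
                raise ValueError(f"t*={t} outside the scan span [0, {self.scan_minutes})")
        if not 0 <= self.reference_t_star < self.scan_minutes:
            raise ValueError("reference t* outside the scan span")

    @property
    def generation_seed(self) -> int:
        return self.seed

    @property
    def validation_seed(self) -> int:
        return self.seed + 1000

    @property
    def fit_seed(self) -> int:
        return self.seed + 2000

    @property
    def phantom_seed(self) -> int:
        return self.seed + 3000

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_generation": self.n_generation,
            "n_validation": self.n_validation,
            "windows": [list(w) for w in self.windows],
            "t_stars": list(self.t_stars),
            "reference_t_star": self.reference_t_star,
            "noise_level": self.noise_level,
            "cv": self.cv,
            "n_tumors": self.n_tumors,
            "phantom_dims": list(self.phantom_dims),
            "scan_minutes": self.scan_minutes,
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "windows" in doc:
            doc["windows"] = tuple(tuple(float(x) for x in w) for w in doc["windows"])
        if "t_stars" in doc:
            doc["t_stars"] = tuple(float(t) for t in doc["t_stars"])
        if "phantom_dims" in doc:
            doc["phantom_dims"] = tuple(int(d) for d in doc["phantom_dims"])
        return cls(**doc)
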