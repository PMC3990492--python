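"""Run configuration: validated parameter bundle for end-to-end runs.

A flat YAML file (or keyword overrides) carries every tunable: group names
and admixture proportions, generations, HMM crossover rate and spurious-CSV
floor, sequencing error and dosage threshold, refinement settings, seeds and
paths.  Flags override only unset config values; a value set in both places
with different content is an error, never a silent override.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np
import yaml


@dataclass
class RunConfig:
    groups: list = field(default_factory=lambda: ["EUR", "NAM", "AFR"])
    theta: list = field(default_factory=lambda: [0.2, 0.0, 0.8])
    generations: int = 6
    lam_hmm: float = 1e-15
    lam_sim: float = 1e-8
    eps_csv: float = 1e-5
    eps_seq: float = 0.01
    tau: float = 0.6
    buffer: int = 10
    n_iter: int = 4
    level: str = "continental"
    seed: int = 0
    panel: str | None = None
    labels: str | None = None
    genotypes: str | None = None
    reads: str | None = None
    csv_table: str | None = None
    truth: str | None = None
    out: str | None = None
    preset: str | None = None

    def validate(self) -> "RunConfig":
        theta = np.asarray(self.theta, dtype=float)
        if len(theta) != len(self.groups):
            raise ValueError("theta must have one entry per group")
        if np.any(theta < 0) or abs(theta.sum() - 1) > 1e-9:
            raise ValueError(f"theta must sum to 1, got {theta.sum():g}")
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        K = len(self.groups)
        if not 0 < self.eps_csv < 1.0 / K:
            raise ValueError("eps_csv must be in (0, 1/K)")
        if not 0 < self.eps_seq < 0.5:
            raise ValueError("eps_seq must be in (0, 0.5)")
        if self.lam_hmm <= 0 or self.lam_sim <= 0:
            raise ValueError("crossover rates must be positive")
        if self.n_iter < 0 or self.buffer < 0:
            raise ValueError("n_iter and buffer must be >= 0")
        if self.level not in ("continental", "population"):
            raise ValueError("level must be 'continental' or 'population'")
        return self

    @classmethod
    def load(cls, path=None, **overrides) -> "RunConfig":
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in overrides.items():
            if v is None:
                continue
            if k in data and data[k] != v:
                raise ValueError(
                    f"conflicting values for {k!r}: config has {data[k]!r}, flag has {v!r}")
            data[k] = v
        cfg = cls(**data)
        if cfg.preset is not None:
            from .simulate import PRESETS

            model = PRESETS[cfg.preset]
            cfg.groups = list(model.groups)
            cfg.theta = list(model.theta)
            cfg.generations = model.generations
        return cfg.validate()

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
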