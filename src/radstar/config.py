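"""Composed run configuration with lossless YAML round-tripping.

One document drives the whole workflow (simulate -> undersample ->
reconstruct), mirroring the CLI flags; unknown keys are rejected so typos
fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import __version__
from .evaluate import StudyProfile
from .phantom import DEFAULT_ECHO_TIMES_MS, PhantomConfig
from .recon import ReconConfig


@dataclass
class RunConfig:
    seed: int = 0
    noise_level: float = 0.0
    delay_dwell: tuple[float, float] = (0.0, 0.0)
    grid_size: int = 256
    n_coils: int = 8
    n_spokes: int = 402
    n_readout: int = 512
    echo_times_ms: tuple = DEFAULT_ECHO_TIMES_MS
    scheme: str = "full"
    keep_fraction: float = 0.5
    mode: str = "joint"
    lam: float = 1.0
    max_outer_iters: int = 10
    version: str = __version__

    def phantom_config(self) -> PhantomConfig:
        return PhantomConfig(
            noise_level=self.noise_level,
            seed=self.seed,
            echo_times_ms=tuple(self.echo_times_ms),
            delay_dwell=tuple(self.delay_dwell),
            grid_size=self.grid_size,
            n_coils=self.n_coils,
        )

    def recon_config(self) -> ReconConfig:
        return ReconConfig(
            mode=self.mode, lam=self.lam, max_outer_iters=self.max_outer_iters,
            seed=self.seed,
        )

    def profile(self) -> StudyProfile:
        return StudyProfile(
            grid_size=self.grid_size,
            n_spokes=self.n_spokes,
            n_readout=self.n_readout,
            n_coils=self.n_coils,
            echo_times_ms=tuple(self.echo_times_ms),
            keep_fraction=self.keep_fraction,
            max_outer_iters=self.max_outer_iters,
        )

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        doc["delay_dwell"] = list(self.delay_dwell)
        doc["echo_times_ms"] = list(self.echo_times_ms)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("delay_dwell", "echo_times_ms"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)
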