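"""Run configuration: validated settings shared by the CLI workflows.

Configs live in TOML; command-line flags override file values.  A frozen
copy of the resolved configuration (plus its hash) is embedded in every
output's provenance block, so any result can be traced to the exact
settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__


@dataclass
class RunConfig:
    cutoff_A: float = 30.0
    restarts: int = 5
    seed: int = 0
    kernel_bounds: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)  # pigment_type -> gamma
    units: dict = field(
        default_factory=lambda: {
            "distance": "angstrom", "charge": "e", "energy": "eV",
            "potential": "e/angstrom", "polarizability": "angstrom^3",
        }
    )

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise ValueError("cutoff_A must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        for k, g in self.gamma.items():
            if g <= 0:
                raise ValueError(f"gamma for {k!r} must be positive")
        for name, b in self.kernel_bounds.items():
            if len(b) != 2 or b[0] <= 0 or b[1] <= b[0]:
                raise ValueError(f"bad bounds for {name!r}: {b}")
        self.kernel_bounds = {k: tuple(v) for k, v in self.kernel_bounds.items()}

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def provenance(self, command: str, extra: dict | None = None) -> dict:
        block = {
            "command": command,
            "config": self.to_dict(),
            "config_hash": self.hash(),
            "seed": self.seed,
            "version": __version__,
        }
        if extra:
            block.update(extra)
        return block


def load_config(path=None, **overrides) -> RunConfig:
    """Load a TOML config (if given) and apply flag overrides."""
    data: dict = {}
    if path is not None:
        data = tomllib.loads(Path(path).read_text())
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
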