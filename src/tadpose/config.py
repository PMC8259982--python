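"""Run configuration: defaults, YAML round-trip, and the run manifest.

Every default equals the analysis' printed parameters: 2 Mb flanking window,
HI <= 10% flag, 75th-percentile phenotype gate, fold-change thresholds
1.5 / 0.66, per-well alpha 0.05 with no multiple-testing adjustment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "write_manifest"]


@dataclass
class RunConfig:
    window: int = 2_000_000
    hi_threshold: float = 10.0
    percentile_gate: float = 75.0
    combine: str = "and"
    weights: list = field(default_factory=lambda: [1.0, 1.0, 1.0, 1.0, 1.0])
    contact_cap: int = 5
    elevated: float = 1.5
    decreased: float = 0.66
    housekeeping: str = "TBP"
    alpha: float = 0.05
    adjust: str = "none"
    statistic: str = "endpoint"
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> "RunConfig":
        if self.window < 0:
            raise ValueError("config field 'window' must be >= 0")
        if not 0 <= self.hi_threshold <= 100:
            raise ValueError("config field 'hi_threshold' must be in [0, 100]")
        if not 0 <= self.percentile_gate <= 100:
            raise ValueError("config field 'percentile_gate' must be in [0, 100]")
        if self.combine not in ("and", "or"):
            raise ValueError("config field 'combine' must be 'and' or 'or'")
        if len(self.weights) != 5:
            raise ValueError("config field 'weights' must have 5 entries")
        if not 0 < self.decreased < self.elevated:
            raise ValueError(
                "config fields 'decreased' < 'elevated' must hold with both > 0"
            )
        if not 0 <= self.alpha <= 1:
            raise ValueError("config field 'alpha' must be in [0, 1]")
        if self.adjust not in ("none", "bh"):
            raise ValueError("config field 'adjust' must be 'none' or 'bh'")
        if self.statistic not in ("endpoint", "slope", "auc"):
            raise ValueError(
                "config field 'statistic' must be 'endpoint', 'slope' or 'auc'"
            )
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: Union[str, Path],
    config: RunConfig,
    inputs: Optional[dict] = None,
    stage: str = "",
) -> Path:
    """Write the run manifest (config, seed, version, input checksums)."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(path) for name, path in (inputs or {}).items()
        },
    }
    path = outdir / (f"manifest_{stage}.json" if stage else "manifest.json")
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
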