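"""Design configuration: flat key=value files, defaults, seed fan-out."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from .primers import AnnealingParams, PCRConditions, PrimerOptima
from .scoring import QCThresholds


def stage_seed(root_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) from one global seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class DesignConfig:
    """Everything the design pipeline needs besides the genome and feature."""

    motif: str = "N{17}|N{3}>NGG"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    arm_length: int = 50
    max_expansion: int = 4096
    expansion_step: int = 50
    min_genome_distance: int = 6
    annealing: AnnealingParams = field(default_factory=AnnealingParams)
    optima: PrimerOptima = field(default_factory=PrimerOptima)
    pcr_conditions: PCRConditions = field(default_factory=PCRConditions)
    max_amplicon: int = 5000
    outer_span: int = 500
    amp_window: int = 60
    rng_seed: int = 0
    ontarget_scorer: str = "surrogate"
    output_dir: str = "tagback_out"

    _NESTED = {
        "thresholds": QCThresholds,
        "annealing": AnnealingParams,
        "optima": PrimerOptima,
        "pcr_conditions": PCRConditions,
    }

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                val = getattr(self, f.name)
                if f.name in self._NESTED:
                    for sub in dataclasses.fields(val):
                        fh.write(f"{f.name}.{sub.name}={getattr(val, sub.name)}\n")
                else:
                    fh.write(f"{f.name}={val}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "DesignConfig":
        flat: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                flat[key.strip()] = value.strip()
        return cls.from_flat(flat)

    @classmethod
    def from_flat(cls, flat: dict[str, str]) -> "DesignConfig":
        kwargs: dict = {}
        nested: dict[str, dict] = {k: {} for k in cls._NESTED}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in flat.items():
            if "." in key:
                group, sub = key.split(".", 1)
                if group not in cls._NESTED:
                    raise KeyError(f"unknown config group {group!r}")
                nested[group][sub] = value
            else:
                if key not in types:
                    raise KeyError(f"unknown config key {key!r}")
                kwargs[key] = _coerce(value, getattr(cls(), key))
        for group, sub_cls in cls._NESTED.items():
            if nested[group]:
                defaults = sub_cls()
                sub_kwargs = {
                    k: _coerce(v, getattr(defaults, k)) for k, v in nested[group].items()
                }
                kwargs[group] = dataclasses.replace(defaults, **sub_kwargs)
        return cls(**kwargs)


def _coerce(value: str, template):
    if isinstance(template, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(template, int):
        return int(value)
    if isinstance(template, float):
        return float(value)
    return value
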