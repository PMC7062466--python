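"""Run configuration: schema-validated YAML with fully documented defaults.

Every unstated pipeline constant lives here so that a run can disclose its
effective configuration next to its outputs. Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .filters import OffTargetPolicy
from .genome_io import FixtureSpec
from .oligo_cloning import CloningParts
from .pair_select import ScoringWeights


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


@dataclass(frozen=True)
class SamplingConfig:
    max_pairs: int = 10_000
    seed: int = 0
    pairs_per_gene: int = 2
    disjoint_pairs: bool = True

    def __post_init__(self) -> None:
        if self.max_pairs < 1:
            raise ConfigError("sampling.max_pairs must be positive")
        if not 0 <= self.seed < 2**31:
            raise ConfigError("sampling.seed must be in [0, 2^31)")


@dataclass(frozen=True)
class RunConfig:
    offtarget: OffTargetPolicy = field(default_factory=OffTargetPolicy)
    scoring: ScoringWeights = field(default_factory=ScoringWeights)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    cloning: CloningParts = field(default_factory=CloningParts)
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    rounding: str = "half_away"

    def __post_init__(self) -> None:
        if self.rounding not in ("half_away", "floor"):
            raise ConfigError("rounding must be 'half_away' or 'floor'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["offtarget"]["pams_considered"] = sorted(self.offtarget.pams_considered)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def write_effective(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_SECTIONS = {
    "offtarget": OffTargetPolicy,
    "scoring": ScoringWeights,
    "sampling": SamplingConfig,
    "cloning": CloningParts,
    "fixture": FixtureSpec,
}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    if cls is OffTargetPolicy and "pams_considered" in data:
        data = dict(data, pams_considered=frozenset(data["pams_considered"]))
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {section!r} configuration: {e}") from e


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; missing file or sections fall back to defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"rounding"}
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    kwargs["rounding"] = raw.get("rounding", "half_away")
    return RunConfig(**kwargs)
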