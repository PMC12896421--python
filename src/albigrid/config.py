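"""Shared YAML configuration for the command-line interface.

A single file with optional nested sections, one per component::

    albi:    {score_decimals: 2, ...}
    grid:    {step: 0.1, ...}
    rules:   {albumin_low: 3.5, ...}
    filters: {apply_cpb_combo_exclusion: true, ...}
    synth:   {n_patients: 10000, seed: 7, zone_weights: {Al-High-1: 3625, ...}}

Unknown keys raise rather than being silently ignored; command-line
flags override file values.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core import AlbiParameters
from .errors import InvalidInputError
from .grid import GridSpec
from .pipeline import FilterConfig
from .synth import SyntheticCohortConfig
from .zones import Zone, ZoneRuleSet

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    """Bundle of all component configurations plus run metadata."""

    albi: AlbiParameters = field(default_factory=AlbiParameters)
    grid: GridSpec = field(default_factory=GridSpec)
    rules: ZoneRuleSet = field(default_factory=ZoneRuleSet)
    filters: FilterConfig = field(default_factory=FilterConfig)
    synth: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)

    def config_hash(self) -> str:
        """Short digest identifying this configuration in output headers."""
        text = repr(
            tuple(
                sorted(
                    (f.name, repr(getattr(self, f.name)))
                    for f in dataclasses.fields(self)
                )
            )
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


_SECTIONS = {
    "albi": AlbiParameters,
    "grid": GridSpec,
    "rules": ZoneRuleSet,
    "filters": FilterConfig,
    "synth": SyntheticCohortConfig,
}


def _build_section(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidInputError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    kwargs = dict(data)
    # zone-weight maps are keyed by zone label in YAML
    for key in ("zone_weights",):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = {Zone(k): v for k, v in kwargs[key].items()}
    if "subgroup_zone_weights" in kwargs and kwargs["subgroup_zone_weights"]:
        kwargs["subgroup_zone_weights"] = {
            sub: {Zone(k): v for k, v in weights.items()}
            for sub, weights in kwargs["subgroup_zone_weights"].items()
        }
    if "cld_codes" in kwargs:
        kwargs["cld_codes"] = frozenset(kwargs["cld_codes"])
    return cls(**kwargs)


def load_run_config(path: str | Path | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; missing file/sections use defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise InvalidInputError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, raw.get(name) or {})
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)
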