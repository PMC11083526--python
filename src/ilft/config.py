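"""Threshold configuration.

All trigger thresholds, score cutoffs and formula coefficients live in one
YAML file so another laboratory's reference limits can be substituted without
touching code. :func:`load_thresholds` reads the packaged defaults and merges
any site overrides on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["Thresholds", "load_thresholds", "DEFAULT_CONFIG"]

DEFAULT_CONFIG = "default_thresholds.yaml"


class ConfigError(ValueError):
    """A threshold key is missing or has an invalid value."""


@dataclass(frozen=True)
class Thresholds:
    """Every configurable cutoff used by the engine. Units in the YAML comments."""

    alt_trigger: float
    alt_marked: float
    alp_url: float
    alp_full_cascade: float
    ggt_url: float
    bili_mild_low: float
    bili_mild_high: float
    crp_age_max: int

    fib4_low: float
    fib4_high: float
    nfs_low: float
    nfs_high: float

    elf_moderate: float
    elf_severe: float
    elf_cirrhosis: float
    elf_urgent: float
    elf_intercept: float
    elf_coef_ha: float
    elf_coef_piiinp: float
    elf_coef_timp1: float

    a1at_deficiency: float
    transferrin_sat_high: float
    crp_elevated: float
    caeruloplasmin_low: float
    conjugated_fraction: float
    haptoglobin_low: float

    malignancy_age: int
    malignancy_alp: float
    malignancy_platelets: float

    legacy_nomenclature: bool = False

    def __post_init__(self) -> None:
        if not self.alp_url < self.alp_full_cascade:
            raise ConfigError("alp_url must be below alp_full_cascade")
        if not self.bili_mild_low < self.bili_mild_high:
            raise ConfigError("bili_mild_low must be below bili_mild_high")
        if not self.fib4_low < self.fib4_high:
            raise ConfigError("fib4_low must be below fib4_high")
        if not self.elf_moderate < self.elf_severe < self.elf_cirrhosis:
            raise ConfigError("ELF band boundaries must be increasing")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not isinstance(v, bool) and not math.isfinite(v):
                raise ConfigError(f"threshold {f.name!r} is not finite")


def _default_mapping() -> dict:
    text = resources.files("ilft.data").joinpath(DEFAULT_CONFIG).read_text()
    return yaml.safe_load(text)


def load_thresholds(path: str | Path | None = None) -> Thresholds:
    """Load thresholds, merging an optional override file onto the defaults.

    Parameters
    ----------
    path:
        Optional YAML file. Keys present override the packaged defaults;
        an unknown key is a hard error so typos cannot silently pass.
    """
    mapping = _default_mapping()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(Thresholds)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        mapping.update(overrides)
    missing = {f.name for f in fields(Thresholds)} - set(mapping) - {"legacy_nomenclature"}
    if missing:
        raise ConfigError(f"config missing threshold keys: {sorted(missing)}")
    return Thresholds(**mapping)
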