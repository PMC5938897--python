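"""Runtime configuration with embedded defaults.

A single optional TOML file can override reader and repair settings::

    [reader]
    dpi = 300
    ink_threshold = 0.02

    [repair]
    cutoff = 3

    [training]
    seed = 1405
    n_per_class = 150
    jitter = 1.0

Unknown sections or keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, fields, replace
from pathlib import Path

from .glyphs import DEFAULT_INK_THRESHOLD
from .pipeline import DEFAULT_TRAIN_N, DEFAULT_TRAIN_SEED
from .repair import DEFAULT_REPAIR_CUTOFF
from .vision import DEFAULT_DPI

__all__ = ["Config", "load_config"]

_SCHEMA = {
    "reader": {"dpi": "dpi", "ink_threshold": "ink_threshold"},
    "repair": {"cutoff": "repair_cutoff"},
    "training": {
        "seed": "train_seed",
        "n_per_class": "train_n",
        "jitter": "train_jitter",
    },
}


@dataclass(frozen=True)
class Config:
    dpi: int = DEFAULT_DPI
    ink_threshold: float = DEFAULT_INK_THRESHOLD
    repair_cutoff: int = DEFAULT_REPAIR_CUTOFF
    train_seed: int = DEFAULT_TRAIN_SEED
    train_n: int = DEFAULT_TRAIN_N
    train_jitter: float = 1.0

    def validate(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if not 0 <= self.ink_threshold < 1:
            raise ValueError("ink_threshold must be in [0, 1)")
        if self.repair_cutoff < 0:
            raise ValueError("repair cutoff must be non-negative")


def load_config(path: str | Path | None = None) -> Config:
    """Defaults, optionally overridden from a TOML file."""
    config = Config()
    if path is None:
        return config
    doc = tomllib.loads(Path(path).read_text(encoding="utf-8"))
    updates: dict[str, object] = {}
    for section, values in doc.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section [{section}]")
        if not isinstance(values, dict):
            raise ValueError(f"[{section}] must be a table")
        for key, value in values.items():
            if key not in _SCHEMA[section]:
                raise ValueError(f"unknown config key {section}.{key}")
            updates[_SCHEMA[section][key]] = value
    config = replace(config, **updates)
    config.validate()
    return config
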