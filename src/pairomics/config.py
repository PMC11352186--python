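"""YAML-backed run configuration.

Flat sections mirror the pipeline stages; unknown keys are rejected so
typos fail fast.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .preprocess import PreprocessOptions
from .network import NetworkOptions
from .synthetic import SimulationConfig


@dataclasses.dataclass
class DiffOptions:
    alpha: float = 0.05


@dataclasses.dataclass
class SignatureOptions:
    fc_cutoff: float = 1.5
    alpha_mix: float = 0.5
    n_lambda: int = 100
    cv_folds: int = 3


@dataclasses.dataclass
class EvaluateOptions:
    n_components: int = 2
    pca_scope: str = "per_fold"
    kernel: str = "best"


@dataclasses.dataclass
class RunConfig:
    simulate: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    preprocess: PreprocessOptions = dataclasses.field(default_factory=PreprocessOptions)
    diff: DiffOptions = dataclasses.field(default_factory=DiffOptions)
    signature: SignatureOptions = dataclasses.field(default_factory=SignatureOptions)
    evaluate: EvaluateOptions = dataclasses.field(default_factory=EvaluateOptions)
    network: NetworkOptions = dataclasses.field(default_factory=NetworkOptions)


def _update(obj, values: dict, section: str) -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in names:
            raise KeyError(f"unknown config key {section}.{key}")
        if isinstance(val, list):
            val = tuple(val)
        setattr(obj, key, val)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, overriding defaults section by section."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for section, values in raw.items():
        if not hasattr(cfg, section):
            raise KeyError(f"unknown config section {section!r}")
        _update(getattr(cfg, section), values or {}, section)
    return cfg
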