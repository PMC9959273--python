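"""YAML/JSON configuration for the analysis pipeline.

Every numeric default of the pipeline — medium constants, probe geometry,
Hamaker constant, tail policy, slope threshold, phase tolerance, Sauerbrey
coefficient, Monte-Carlo seed — can be overridden from a config file::

    medium:
      rel_permittivity: 78.5
      ionic_strength: 1.0      # mol/m^3
      temperature: 298.15
    geometry:
      sphere_radius: 5000      # nm
    hamaker: 3.6e-21           # J
    slope_threshold: 1.8e-3    # nN/nm
    tail_policy:
      d_min: null              # nm; null -> 2 / kappa_init
      min_force: 1.0e-2        # nN
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fitting import TailPolicy
from .phase import DEFAULT_COATING_AREAL_MASS, DEFAULT_SAUERBREY_COEFF
from .physics import DEFAULT_HAMAKER, DEFAULT_SLOPE_THRESHOLD, Medium, ProbeGeometry

__all__ = ["AnalysisConfig", "load_config"]

#: Default seed for Monte-Carlo style analyses.
DEFAULT_SEED = 20230415


@dataclass
class AnalysisConfig:
    """Bundle of every tunable the pipeline exposes."""

    medium: Medium = field(default_factory=Medium)
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    hamaker: float = DEFAULT_HAMAKER
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD
    tail_policy: TailPolicy = field(default_factory=TailPolicy)
    baseline_window_fraction: float = 0.2
    phase_tol: float = 0.02
    sauerbrey_coeff: float = DEFAULT_SAUERBREY_COEFF
    coating_areal_mass: float = DEFAULT_COATING_AREAL_MASS
    seed: int = DEFAULT_SEED


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file.

    Unspecified keys keep their defaults; unknown keys raise.
    """
    text = Path(path).read_text()
    if Path(path).suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    raw = raw or {}
    cfg = AnalysisConfig()
    known = {
        "medium": lambda v: Medium(**v),
        "geometry": lambda v: ProbeGeometry(**v),
        "tail_policy": lambda v: TailPolicy(**v),
        "hamaker": float,
        "slope_threshold": float,
        "baseline_window_fraction": float,
        "phase_tol": float,
        "sauerbrey_coeff": float,
        "coating_areal_mass": float,
        "seed": int,
    }
    for key, value in raw.items():
        if key not in known:
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, known[key](value))
    return cfg
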