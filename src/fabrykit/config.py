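"""Text-config (YAML) round-tripping for the simulator, registry, and scoring.

A single config file holds three sections:

* ``simulation`` — :class:`~fabrykit.simulate.SimConfig` fields
* ``registry`` — :class:`~fabrykit.phenotypes.CodeRegistry` code prefixes
* ``scoring`` — :class:`~fabrykit.fdf.ScoringMap` band edges and weights

Any omitted section or field falls back to the package default, so a config
file only needs to state what it changes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .fdf import ScoringMap
from .phenotypes import CodeRegistry
from .simulate import SimConfig

__all__ = ["AppConfig", "load_config", "default_config_dict", "write_default_config"]


@dataclass
class AppConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    registry: CodeRegistry = field(default_factory=CodeRegistry)
    scoring: ScoringMap = field(default_factory=ScoringMap)


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigurationError(f"unknown {name} config field(s): {sorted(unknown)}")
    kwargs = dict(section)
    if cls is ScoringMap:
        for key in ("egfr_bands", "uacr_bands"):
            if key in kwargs:
                kwargs[key] = [tuple(pair) for pair in kwargs[key]]
    if cls is CodeRegistry:
        for key in ("domain_codes", "riskfactor_codes"):
            if key in kwargs:
                kwargs[key] = {k: set(v) for k, v in kwargs[key].items()}
    return cls(**kwargs)


def load_config(path) -> AppConfig:
    """Read a YAML config file; missing sections use package defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping at top level")
    unknown = set(raw) - {"simulation", "registry", "scoring"}
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
    return AppConfig(
        simulation=_build(SimConfig, raw.get("simulation", {}) or {}, "simulation"),
        registry=_build(CodeRegistry, raw.get("registry", {}) or {}, "registry"),
        scoring=_build(ScoringMap, raw.get("scoring", {}) or {}, "scoring"),
    )


def default_config_dict() -> dict:
    sim = asdict(SimConfig())
    sim["age_range"] = list(sim["age_range"])
    sim["renal_event_egfr"] = list(sim["renal_event_egfr"])
    sim["renal_event_uacr"] = list(sim["renal_event_uacr"])
    sim["lab_calibration"] = {
        sex: {lab: list(ms) for lab, ms in cal.items()}
        for sex, cal in sim["lab_calibration"].items()
    }
    reg = CodeRegistry()
    scoring = ScoringMap()
    return {
        "simulation": sim,
        "registry": {
            "domain_codes": {d: sorted(ps) for d, ps in reg.domain_codes.items()},
            "riskfactor_codes": {f: sorted(ps) for f, ps in reg.riskfactor_codes.items()},
            "severity_weights": dict(sorted(reg.severity_weights.items())),
        },
        "scoring": {
            "egfr_bands": [list(b) for b in scoring.egfr_bands],
            "uacr_bands": [list(b) for b in scoring.uacr_bands],
            "cardiac_weights": scoring.cardiac_weights,
            "cerebrovascular_weights": scoring.cerebrovascular_weights,
            "pain_weights": scoring.pain_weights,
            "domain_max": scoring.domain_max,
            "dichotomization_threshold": scoring.dichotomization_threshold,
        },
    }


def write_default_config(path) -> None:
    """Write the fully spelled-out default config as editable YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(default_config_dict(), fh, sort_keys=False, default_flow_style=None)
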