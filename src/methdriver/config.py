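"""Run configuration: YAML file plus CLI overrides, echoed to a manifest."""

from __future__ import annotations

import json
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .gma import GmaConfig
from .pipeline import PrimaryConfig
from .simulate import SimConfig

_SECTIONS = {"primary": PrimaryConfig, "gma": GmaConfig, "simulate": SimConfig}


def load_run_config(path=None, overrides: dict | None = None) -> dict:
    """Build {'primary': PrimaryConfig, 'gma': GmaConfig, 'simulate': SimConfig}
    from an optional YAML file and a flat override mapping.

    YAML layout mirrors the section names; unknown keys are fatal so typos
    cannot silently fall back to defaults.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(_SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections {sorted(unknown)}")
    out = {}
    for section, cls in _SECTIONS.items():
        kwargs = dict(raw.get(section, {}))
        valid = {f.name for f in fields(cls)}
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown {section} config keys {sorted(unknown)}")
        for key, value in (overrides or {}).items():
            if key in valid and value is not None:
                kwargs[key] = value
        out[section] = cls(**kwargs)
    return out


def write_run_manifest(path, configs: dict, extra: dict | None = None) -> None:
    """Echo the effective configuration of a run to JSON."""
    import methdriver
    payload = {name: asdict(cfg) for name, cfg in configs.items()}
    payload["version"] = methdriver.__version__
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
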