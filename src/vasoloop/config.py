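"""Configuration loading: one YAML schema covers plant, scenario and the
controller profiles. ``load_config()`` returns the packaged defaults; pass a
path to override."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_config", "config_hash"]


def load_config(path: str | Path | None = None) -> dict:
    """Load a config mapping (packaged defaults when ``path`` is None)."""
    if path is None:
        text = resources.files("vasoloop.data").joinpath(
            "default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    for section in ("plant", "scenario", "controllers"):
        if section not in cfg:
            raise ValueError(f"config is missing the {section!r} section")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash identifying the reproducibility inputs."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
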