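"""Configuration files, seed derivation and provenance sidecars."""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import yaml

__all__ = ["load_config", "config_get", "stage_seed", "write_provenance"]

# stable per-stage offsets for deriving stage seeds from the master seed
_STAGE_OFFSETS = {
    "screen": 1,
    "signatures": 2,
    "synth": 3,
    "compare": 4,
    "therapy": 5,
    "resist": 6,
}


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} not found")
    data = yaml.safe_load(path.read_text())
    return {} if data is None else data


def config_get(config: dict, key_path: str, default=..., expected_type=None):
    """Fetch a dotted key path ('screen.n'); missing keys without a default
    raise an error naming the full path."""
    node = config
    parts = key_path.split(".")
    for i, part in enumerate(parts):
        if not isinstance(node, dict) or part not in node:
            if default is not ...:
                return default
            missing = ".".join(parts[: i + 1])
            raise KeyError(f"missing config key {missing!r} (wanted {key_path!r})")
        node = node[part]
    if expected_type is not None and not isinstance(node, expected_type):
        raise TypeError(f"config key {key_path!r} must be {expected_type.__name__}")
    return node


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed
    via a spawn-keyed SeedSequence."""
    if stage not in _STAGE_OFFSETS:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=(_STAGE_OFFSETS[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def _package_version() -> str:
    try:
        return version("micromet")
    except PackageNotFoundError:
        return "unknown"


def write_provenance(path, command: str, seed: int | None, config: dict | None = None,
                     extra: dict | None = None) -> Path:
    """JSON sidecar recording command, seed, config hash and version."""
    path = Path(path)
    digest = None
    if config is not None:
        digest = hashlib.md5(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    payload = {
        "command": command,
        "seed": seed,
        "config_md5": digest,
        "micromet_version": _package_version(),
    }
    if extra:
        payload.update(extra)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps(payload, indent=2, default=str))
    return sidecar
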