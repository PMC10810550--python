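"""Run manifests: enough metadata to reproduce any stochastic run exactly
within this implementation (command, full parameter set including defaults
actually used, master seed, version, timestamps, outputs)."""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return obj


def write_manifest(
    path,
    command: str,
    parameters: dict,
    seed: int,
    outputs: list,
    started=None,
    finished=None,
) -> dict:
    from . import __version__

    now = datetime.now(timezone.utc).isoformat()
    manifest = {
        "command": command,
        "parameters": _jsonable(parameters),
        "master_seed": int(seed),
        "software": {"package": "firefreq", "version": __version__},
        "started": started or now,
        "finished": finished or now,
        "outputs": [str(p) for p in outputs],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
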