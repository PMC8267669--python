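"""Run manifests: reproducibility records written next to every output.

A manifest captures the tool version, the full configuration, SHA-256
digests of every input file, any seeds, and a timestamp. Two runs with
the same inputs, configuration and seed produce identical manifests
except for the timestamp, so outputs are auditable byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_manifest(
    config: Mapping,
    inputs: Sequence[str | Path],
    seed: int | None = None,
    command: str = "",
) -> dict:
    """Build a manifest record; raises before any output if an input is missing."""
    digests = {}
    for path in inputs:
        p = Path(path)
        if not p.is_file():
            raise FileNotFoundError(f"manifest input does not exist: {p}")
        digests[str(p)] = file_digest(p)
    return {
        "tool": "depmarker",
        "version": __version__,
        "command": command,
        "config": dict(config),
        "inputs": digests,
        "seed": seed,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def write_manifest(manifest: Mapping, out_dir: str | Path, name: str = "manifest.json") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path
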