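"""Run manifests: every stage's parameters, seeds and input checksums.

A manifest makes a run reproducible: re-running with the recorded parameters
and seeds reproduces deterministic outputs byte-identically.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

from . import __version__

__all__ = ["RunManifest"]


class RunManifest:
    def __init__(self, command: str, params: dict):
        self.data = {
            "tool": "straintrack",
            "version": __version__,
            "command": command,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            "params": params,
            "inputs": {},
            "outputs": [],
        }

    def add_input(self, path) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.data["inputs"][str(p)] = h

    def add_output(self, path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str) + "\n")
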