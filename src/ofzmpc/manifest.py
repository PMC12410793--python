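"""Run manifests: enough metadata to re-execute a run bit-identically."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__

__all__ = ["RunManifest"]


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    config_provenance: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # name -> sha256
    outputs: dict = field(default_factory=dict)  # name -> sha256
    timings_s: dict = field(default_factory=dict)
    version: str = __version__
    extra: dict = field(default_factory=dict)

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _digest(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _digest(path)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings_s[name] = time.perf_counter() - self.t0
                return False

        return _Timer()

    def write(self, path) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "package_version": self.version,
            "config": self.config,
            "config_provenance": self.config_provenance,
            "inputs_sha256": self.inputs,
            "outputs_sha256": self.outputs,
            "timings_s": self.timings_s,
            **({"extra": self.extra} if self.extra else {}),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
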