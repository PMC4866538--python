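"""Run manifests and reproducible per-stage seeding.

Every CLI run writes a manifest recording the tool version, the full
parameter snapshot, digests of the input files and the seed, so that a
diff of two manifests explains any diff between their outputs.  A single
global seed fans out to per-stage streams through a fixed counter, which
keeps stages independently re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

VERSION = "0.1.0"

_STAGE_COUNTERS = {
    "simulate": 0, "filter": 1, "glmm": 2, "diffstat": 3,
    "scan": 4, "enrich": 5, "pbs": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible stream for a named pipeline stage."""
    if stage not in _STAGE_COUNTERS:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGE_COUNTERS[stage],))
    return np.random.default_rng(ss)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, stage: str, params: dict,
                   inputs: dict[str, str | Path] | None = None,
                   seed: int | None = None) -> dict:
    manifest = {
        "tool": "poolsel", "version": VERSION, "stage": stage,
        "seed": seed, "parameters": params,
        "inputs": {name: {"path": str(p), "sha256": file_digest(p)}
                   for name, p in (inputs or {}).items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
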