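"""CSV/JSON round-trip of sample tables and distance reports.

Sample tables are written as plain CSV (``experiment,time,replicate,value``)
with shortest-round-trip float formatting, so write-then-read reproduces the
values exactly.  A sidecar ``<name>.meta.json`` records role, normalisation
divisors, seed and generating configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .distances import HierarchicalDistance
from .protocols import SampleTable

__all__ = ["write_sample_table", "read_sample_table", "write_distance_report", "meta_path"]


def meta_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.name + ".meta.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_sample_table(table: SampleTable, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    meta = {
        "role": table.role,
        "normalised": table.normalised,
        "divisors": table.divisors,
        "meta": _jsonable(table.meta),
    }
    meta_path(path).write_text(json.dumps(meta, indent=2))


def read_sample_table(path) -> SampleTable:
    path = Path(path)
    frame = pd.read_csv(path)
    mp = meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
        return SampleTable(
            frame=frame,
            role=meta.get("role", "model"),
            normalised=meta.get("normalised", False),
            divisors=meta.get("divisors", {}),
            meta=meta.get("meta", {}),
        )
    return SampleTable(frame=frame)


def write_distance_report(result: HierarchicalDistance, path, extra: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = result.to_dict()
    if extra:
        payload["config"].update(_jsonable(extra))
    path.write_text(json.dumps(payload, indent=2))
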