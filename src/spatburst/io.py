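"""Plain-text import/export of point patterns, geometry and results.

Datasets are exchanged as two tables: a pattern table with one row per
transcript (``cell_id, x`` — plus ``y`` in 2D) and a geometry side-car
with one row per cell (``cell_id, R, z``).  Cells with zero transcripts
appear only in the geometry table.  A JSON run-manifest carries the
generative parameters and seed.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from .core import Domain1D, PointPattern

__all__ = [
    "write_patterns_csv",
    "read_patterns_csv",
    "write_manifest",
    "read_manifest",
]


def write_patterns_csv(patterns: list[PointPattern], pattern_path, geometry_path) -> None:
    """Write a 1D population to a pattern CSV and a geometry CSV."""
    rows = []
    geo = []
    for cid, pat in enumerate(patterns):
        geo.append({"cell_id": cid, "R": pat.domain.R, "z": float(pat.z)})
        for x in np.asarray(pat.positions, dtype=float):
            rows.append({"cell_id": cid, "x": x})
    pd.DataFrame(rows, columns=["cell_id", "x"]).to_csv(pattern_path, index=False)
    pd.DataFrame(geo, columns=["cell_id", "R", "z"]).to_csv(geometry_path, index=False)


def read_patterns_csv(pattern_path, geometry_path, boundary: str = "robin") -> list[PointPattern]:
    """Read a 1D population written by :func:`write_patterns_csv`."""
    pts = pd.read_csv(pattern_path)
    geo = pd.read_csv(geometry_path).set_index("cell_id").sort_index()
    grouped = pts.groupby("cell_id")["x"]
    patterns = []
    for cid, row in geo.iterrows():
        x = grouped.get_group(cid).to_numpy() if cid in grouped.groups else np.empty(0)
        patterns.append(
            PointPattern(x, Domain1D(float(row["R"]), boundary), float(row["z"]))
        )
    return patterns


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return "inf" if math.isinf(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
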