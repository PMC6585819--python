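"""File I/O: measurement CSVs, response configs, reports, manifests.

The measurement CSV has one row per condition per replicate: factor
columns carry physical level values, a ``replicate`` column the 1-based
replicate index, and one column per response; an empty cell marks a
missing well.  Floats are written with shortest round-trip precision so
a write/read cycle is bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .grid import (
    Condition,
    GridSpace,
    MeasurementTable,
    ResponseDef,
    build_grid,
    code_levels,
)
from .weights import WeightGrid


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a measurement table to CSV (empty cells for missing wells)."""
    factor_names = [f.name for f in table.grid.factors]
    rows = []
    for cond in sorted(table.entries):
        phys = table.grid.physical(cond)
        for ri, rep in enumerate(table.entries[cond], start=1):
            row: dict[str, object] = dict(zip(factor_names, phys))
            row["replicate"] = ri
            for name, v in zip(table.response_names, rep):
                row[name] = "" if math.isnan(v) else repr(float(v))
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_measurements(
    path: str | Path,
    response_names: Sequence[str],
    grid: GridSpace | None = None,
) -> MeasurementTable:
    """Read a measurement CSV written by :func:`write_measurements`.

    Without an explicit grid, factors are inferred from the distinct
    values of every column left of ``replicate``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "replicate" not in df.columns:
        raise ValueError(f"{path}: no 'replicate' column")
    rep_idx = list(df.columns).index("replicate")
    factor_names = list(df.columns[:rep_idx])
    for name in response_names:
        if name not in df.columns:
            raise ValueError(f"{path}: missing response column {name!r}")
    if grid is None:
        grid = build_grid(
            [code_levels(sorted(df[n].unique()), name=n) for n in factor_names]
        )

    entries: dict[Condition, list[tuple[float, ...]]] = {}
    missing: set[tuple[Condition, str]] = set()
    for i, row in df.iterrows():
        try:
            cond = tuple(
                f.code_of(float(row[f.name])) for f in grid.factors
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
        vals = []
        for name in response_names:
            v = row[name]
            if pd.isna(v):
                vals.append(float("nan"))
                missing.add((cond, name))
            else:
                vals.append(float(v))
        entries.setdefault(cond, []).append(tuple(vals))
    return MeasurementTable(
        grid=grid,
        response_names=tuple(response_names),
        entries={c: tuple(reps) for c, reps in entries.items()},
        missing=frozenset(missing),
    )


def response_defs_to_dict(defs: Sequence[ResponseDef]) -> dict:
    out = []
    for d in defs:
        rec = {"name": d.name, "goal": d.goal, "T": d.T, "units": d.units}
        if d.L is not None:
            rec["L"] = d.L
        if d.U is not None:
            rec["U"] = d.U
        out.append(rec)
    return {"responses": out}


def response_defs_from_dict(data: Mapping) -> tuple[ResponseDef, ...]:
    return tuple(
        ResponseDef(
            name=rec["name"],
            goal=rec["goal"],
            T=float(rec["T"]),
            L=float(rec["L"]) if "L" in rec else None,
            U=float(rec["U"]) if "U" in rec else None,
            units=rec.get("units", ""),
        )
        for rec in data["responses"]
    )


def write_response_config(defs: Sequence[ResponseDef], path: str | Path) -> None:
    path = Path(path)
    payload = response_defs_to_dict(defs)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_response_config(path: str | Path) -> tuple[ResponseDef, ...]:
    path = Path(path)
    text = path.read_text()
    data = (
        yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    )
    return response_defs_from_dict(data)


def weight_grid_from_dict(data: Mapping) -> WeightGrid:
    return WeightGrid(levels=tuple(tuple(float(v) for v in lv) for lv in data["weights"]))


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def manifest(config: Mapping, seed: int) -> dict:
    """Reproducibility manifest: seed, config hash, package version."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True).encode()
    return {
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "gridsimplex_version": __version__,
    }
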