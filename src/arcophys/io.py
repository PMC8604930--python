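"""Sweep-bundle I/O and report writing.

The canonical on-disk format is a plain, human-diffable bundle: one CSV per
sweep (columns ``t_ms``, ``y``, ``command``) plus a ``manifest.json``
sidecar carrying units, the sampling interval, protocol metadata, the
package version and the seed of the run.  Units and dt are mandatory on
read; nothing is ever guessed.

Voltages are stored in mV, currents in pA inside files; conversion to nA
for reporting happens in one place (:func:`pa_to_na`).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sweeps import Sweep, SweepSet

__all__ = ["write_sweepset", "read_sweeps", "write_report", "pa_to_na",
           "na_to_pa"]

_MANIFEST = "manifest.json"


def pa_to_na(x):
    return np.asarray(x) * 1e-3


def na_to_pa(x):
    return np.asarray(x) * 1e3


def _file_units(unit: str) -> tuple:
    """(file unit, scale from in-memory to file) for a sweep unit string."""
    if unit == "nA":
        return "pA", 1e3
    return unit, 1.0


def write_sweepset(sweepset: SweepSet, out_dir, seed: int | None = None,
                   force: bool = False) -> Path:
    """Write a sweep bundle; returns the bundle directory.

    Refuses to overwrite an existing manifest unless ``force`` is set.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    man_path = out / _MANIFEST
    if man_path.exists() and not force:
        raise FileExistsError(f"{man_path} exists; pass force=True to replace")
    entries = []
    for i, sw in enumerate(sweepset):
        name = f"sweep_{i:03d}.csv"
        y_unit, y_scale = _file_units(sw.y_units)
        c_unit, c_scale = _file_units(sw.command_units)
        df = pd.DataFrame({"t_ms": sw.t, "y": sw.y * y_scale,
                           "command": sw.command * c_scale})
        df.to_csv(out / name, index=False, float_format="%.9g")
        entries.append({"file": name, "dt_ms": sw.dt,
                        "y_units": y_unit, "command_units": c_unit,
                        "n_samples": len(sw.t),
                        "meta": _jsonable(sw.meta)})
    manifest = {"format": "arcophys-sweep-bundle/1", "version": __version__,
                "seed": seed, "sweeps": entries,
                "meta": _jsonable(sweepset.meta)}
    man_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_sweeps(path) -> SweepSet:
    """Read a sweep bundle written by :func:`write_sweepset`.

    Missing units or dt are a hard error naming the offending sweep.
    """
    p = Path(path)
    man_path = p / _MANIFEST if p.is_dir() else p
    if not man_path.exists():
        raise FileNotFoundError(f"no manifest found at {man_path}")
    manifest = json.loads(man_path.read_text())
    base = man_path.parent
    sweeps = []
    for entry in manifest["sweeps"]:
        name = entry.get("file", "<unnamed>")
        for key in ("dt_ms", "y_units", "command_units"):
            if entry.get(key) is None:
                raise ValueError(f"sweep {name}: missing mandatory field {key!r}")
        df = pd.read_csv(base / name)
        y_unit = entry["y_units"]
        mem_unit, scale = ("nA", 1e-3) if y_unit == "pA" else (y_unit, 1.0)
        c_unit = entry["command_units"]
        cmem_unit, cscale = ("nA", 1e-3) if c_unit == "pA" else (c_unit, 1.0)
        # current-clamp commands are currents and stay in pA in memory
        if c_unit == "pA":
            cmem_unit, cscale = "pA", 1.0
        sw = Sweep(t=df["t_ms"].to_numpy(),
                   y=df["y"].to_numpy() * scale,
                   command=df["command"].to_numpy() * cscale,
                   y_units=mem_unit, command_units=cmem_unit,
                   meta=entry.get("meta", {}))
        if abs(sw.dt - entry["dt_ms"]) > 1e-9:
            raise ValueError(f"sweep {name}: manifest dt {entry['dt_ms']} ms "
                             f"does not match data ({sw.dt} ms)")
        sweeps.append(sw)
    dts = {round(s.dt, 12) for s in sweeps}
    if len(dts) > 1:
        raise ValueError(f"heterogeneous sampling intervals in bundle: {sorted(dts)}")
    return SweepSet(sweeps=sweeps, meta=manifest.get("meta", {}))


def write_report(table: pd.DataFrame, path, column_dict: dict | None = None,
                 force: bool = False) -> Path:
    """Write a tidy CSV report with deterministic ordering.

    ``column_dict`` (column -> description/units) is written alongside as
    ``<name>.columns.json``.  Existing files are an error without ``force``.
    """
    out = Path(path)
    if out.exists() and not force:
        raise FileExistsError(f"{out} exists; pass force=True to replace")
    out.parent.mkdir(parents=True, exist_ok=True)
    table = table.copy()
    table.to_csv(out, index=False, float_format="%.9g")
    if column_dict is not None:
        side = out.with_suffix(out.suffix + ".columns.json")
        side.write_text(json.dumps(column_dict, indent=1, sort_keys=True))
    return out
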