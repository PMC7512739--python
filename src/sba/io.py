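"""Plain-text I/O: extended-XYZ trajectories and '#'-headered tables.

Extended-XYZ is the single canonical trajectory dialect: per frame a particle
count line, a comment line of key=value pairs carrying the cubic box
(``Lattice="L 0 0 0 L 0 0 0 L"``, ase-compatible) plus frame metadata, then
one ``label x y z`` row per particle.  Coordinates are written wrapped into
[0, L0) at full double precision and round-trip exactly.

Curves, fit results and thermodynamic tables are whitespace-separated columns
beneath ``#``-prefixed header lines of the form ``# key = value``; a
``# type = ...`` line dispatches the reader.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np

from .core import (
    ChemPotCurve,
    CompressibilityTable,
    Configuration,
    FitResult,
    FluctuationCurve,
    KBICurveSet,
    KBITable,
    Trajectory,
)

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "write_table",
    "read_table",
]

_FMT = "%.17g"

# key=value tokens; values may be double-quoted (may contain spaces)
_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _frame_to_xyz(config: Configuration, extra: dict[str, Any] | None = None) -> str:
    L = config.box_edge
    lat = f'Lattice="{_FMT % L} 0 0 0 {_FMT % L} 0 0 0 {_FMT % L}"'
    kv = [lat, "Properties=species:S:1:pos:R:3", f"frame={config.frame_index}",
          "pbc=\"T T T\""]
    for k, v in (extra or {}).items():
        kv.append(f"{k}={v}")
    lines = [str(config.n_particles), " ".join(kv)]
    for s, (x, y, z) in zip(config.species, config.positions):
        lines.append(f"{s} {_FMT % x} {_FMT % y} {_FMT % z}")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write an extended-XYZ trajectory (one frame per block)."""
    path = Path(path)
    meta = traj.metadata
    scalar_keys = ("temperature", "density", "seed", "source")
    extra = {k: meta[k] for k in scalar_keys if k in meta and meta[k] is not None}
    with path.open("w") as fh:
        for fr in traj.frames:
            fh.write(_frame_to_xyz(fr, extra))


def read_trajectory(path: str | Path, format_hint: str = "extxyz") -> Trajectory:
    """Read an extended-XYZ trajectory; box metadata is mandatory.

    Raises with the offending frame index when particle counts are
    inconsistent across frames or a frame lacks the box edge.
    """
    if format_hint not in ("extxyz", "xyz"):
        raise ValueError(f"unsupported trajectory format: {format_hint!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Configuration] = []
    meta: dict[str, Any] = {}
    i = 0
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"frame {k}: expected a particle-count line, got "
                             f"{lines[i]!r}")
        if i + 1 + n >= len(lines) + 1 and len(lines) < i + 2 + n:
            raise ValueError(f"frame {k}: truncated frame ({n} particles declared)")
        kv = _parse_comment(lines[i + 1])
        if "Lattice" in kv:
            cell = np.array(kv["Lattice"].split(), dtype=float).reshape(3, 3)
            if not (np.allclose(cell, np.diag(np.diag(cell)))
                    and np.allclose(np.diag(cell), cell[0, 0])):
                raise ValueError(f"frame {k}: only cubic boxes are supported")
            box = float(cell[0, 0])
        elif "box_edge" in kv:
            box = float(kv["box_edge"])
        else:
            raise ValueError(
                f"frame {k}: missing box metadata (Lattice or box_edge); "
                "block analysis is meaningless without L0"
            )
        species = []
        pos = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"frame {k}: malformed particle row {j}")
            species.append(parts[0])
            pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frame_index = int(kv.get("frame", k))
        frames.append(Configuration(pos, np.array(species), box, frame_index))
        for key in ("temperature", "density", "seed"):
            if key in kv and key not in meta:
                meta[key] = float(kv[key]) if key != "seed" else int(float(kv[key]))
        if "source" in kv:
            meta.setdefault("source", kv["source"])
        i += 2 + n
        k += 1
    if not frames:
        raise ValueError(f"no frames found in {path}")
    # Trajectory.__post_init__ enforces constant N / species / box, but catch the
    # count mismatch here to name the frame in file terms
    n0 = frames[0].n_particles
    for k, fr in enumerate(frames):
        if fr.n_particles != n0:
            raise ValueError(
                f"frame {k} of {path} has {fr.n_particles} particles, frame 0 "
                f"has {n0}: inconsistent trajectory"
            )
    return Trajectory(frames, metadata=meta)


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------


def _header(kind: str, meta: dict[str, Any], columns: list[str]) -> str:
    out = ["# sba table", f"# type = {kind}"]
    for k, v in meta.items():
        if isinstance(v, (dict, list, tuple)):
            v = json.dumps(v, default=str)
        out.append(f"# {k} = {v}")
    out.append("# columns: " + " ".join(columns))
    return "\n".join(out) + "\n"


def _read_header(path: Path) -> tuple[str, dict[str, str], np.ndarray]:
    meta: dict[str, str] = {}
    kind = ""
    with path.open() as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        body = line[1:].strip()
        if body.startswith("type ="):
            kind = body.split("=", 1)[1].strip()
        elif "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
        elif body.startswith("columns:"):
            meta["columns"] = body.split(":", 1)[1].strip()
    data = np.loadtxt(path, ndmin=2)
    return kind, meta, data


def write_table(obj, path: str | Path) -> None:
    """Serialize a curve / fit / thermo table to the '#'-headered text format."""
    path = Path(path)
    if isinstance(obj, FluctuationCurve):
        if obj.lambda_grid.size == 0:
            raise ValueError("refusing to write an empty table")
        meta = {"scaled": obj.scaled, **_jsonable(obj.system)}
        head = _header("fluctuation_curve", meta, ["lambda", "value", "stderr",
                                                   "n_blocks"])
        body = np.column_stack([obj.lambda_grid, obj.values, obj.stderr,
                                np.asarray(obj.n_blocks, dtype=float)])
    elif isinstance(obj, KBICurveSet):
        if obj.lambda_grid.size == 0:
            raise ValueError("refusing to write an empty table")
        cols = ["lambda"]
        arrs = [obj.lambda_grid]
        for pair in obj.pairs:
            tag = f"G_{pair[0]}{pair[1]}"
            cols += [tag, tag + "_err"]
            arrs += [obj.values[pair], obj.stderr[pair]]
        meta = {
            "species": json.dumps(list(obj.species)),
            "species_rho": json.dumps(obj.rho),
            **_jsonable(obj.system),
        }
        head = _header("kbi_curves", meta, cols)
        body = np.column_stack(arrs)
    elif isinstance(obj, FitResult):
        names = sorted(obj.params)
        meta = {
            "model_id": obj.model_id,
            "window": json.dumps(list(obj.window)),
            "n_points": obj.n_points,
            "L0": obj.L0,
            "residual_rms": obj.residual_rms,
            "pair": json.dumps(list(obj.pair)) if obj.pair else "null",
            "rho_i": obj.rho_i if obj.rho_i is not None else "null",
            "diagonal": obj.diagonal,
            "param_names": json.dumps(names),
        }
        head = _header("fit_result", meta, ["param_index", "value", "stderr"])
        body = np.column_stack([
            np.arange(len(names), dtype=float),
            [obj.params[n] for n in names],
            [obj.stderr.get(n, np.nan) for n in names],
        ])
    elif isinstance(obj, CompressibilityTable):
        err = obj.chi_err if obj.chi_err is not None else np.full_like(obj.rho, np.nan)
        meta = {"kT": obj.kT, **_jsonable(obj.meta)}
        head = _header("compressibility_table", meta, ["rho", "chi_inf", "chi_err"])
        body = np.column_stack([obj.rho, obj.chi_inf, err])
    elif isinstance(obj, KBITable):
        meta = {"kT": obj.kT, **_jsonable(obj.meta)}
        cols = ["xA", "rhoA", "rhoB", "G_AA", "G_AB", "G_BB"]
        body = np.column_stack([obj.xA, obj.rhoA, obj.rhoB, obj.G_AA, obj.G_AB,
                                obj.G_BB])
        head = _header("kbi_table", meta, cols)
    elif isinstance(obj, ChemPotCurve):
        ex = (obj.delta_mu_excess if obj.delta_mu_excess is not None
              else np.full_like(obj.axis, np.nan))
        err = obj.stderr if obj.stderr is not None else np.full_like(obj.axis, np.nan)
        meta = {
            "axis_name": obj.axis_name,
            "kT": obj.kT,
            "reference": json.dumps(obj.reference, default=str),
            **_jsonable(obj.meta),
        }
        head = _header("chempot_curve", meta,
                       [obj.axis_name, "delta_mu", "delta_mu_excess", "stderr"])
        body = np.column_stack([obj.axis, obj.delta_mu, ex, err])
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    if body.size == 0:
        raise ValueError("refusing to write an empty table")
    with path.open("w") as fh:
        fh.write(head)
        np.savetxt(fh, body, fmt=_FMT)


def _jsonable(meta: dict[str, Any]) -> dict[str, str]:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            continue  # bulky arrays (e.g. energy series) are not header material
        if isinstance(v, (dict, list, tuple)):
            out[k] = json.dumps(v, default=str)
        else:
            out[k] = v
    return out


def _maybe_json(v: str):
    try:
        return json.loads(v)
    except (json.JSONDecodeError, TypeError):
        return v


def read_table(path: str | Path):
    """Read back any table written by :func:`write_table` (round-trip exact)."""
    path = Path(path)
    kind, meta, data = _read_header(path)
    if kind == "fluctuation_curve":
        system = {k: _maybe_json(v) for k, v in meta.items()
                  if k not in ("scaled", "columns")}
        return FluctuationCurve(
            lambda_grid=data[:, 0],
            values=data[:, 1],
            stderr=data[:, 2],
            n_blocks=data[:, 3].astype(int),
            system=system,
            scaled=meta.get("scaled", "False") == "True",
        )
    if kind == "kbi_curves":
        species = json.loads(meta["species"])
        rho = json.loads(meta["species_rho"])
        cols = meta["columns"].split()
        values: dict[tuple[str, str], np.ndarray] = {}
        stderr: dict[tuple[str, str], np.ndarray] = {}
        for ci, name in enumerate(cols):
            if name.startswith("G_") and not name.endswith("_err"):
                pair = (name[2], name[3])
                values[pair] = data[:, ci]
                stderr[pair] = data[:, ci + 1]
        system = {k: _maybe_json(v) for k, v in meta.items()
                  if k not in ("species", "species_rho", "columns")}
        return KBICurveSet(
            lambda_grid=data[:, 0], species=species, values=values,
            stderr=stderr, n_blocks=np.zeros(data.shape[0], dtype=int),
            rho=rho, system=system,
        )
    if kind == "fit_result":
        names = json.loads(meta["param_names"])
        params = {n: float(data[i, 1]) for i, n in enumerate(names)}
        perr = {n: float(data[i, 2]) for i, n in enumerate(names)}
        pair = json.loads(meta["pair"]) if meta["pair"] != "null" else None
        rho_i = None if meta["rho_i"] == "null" else float(meta["rho_i"])
        return FitResult(
            model_id=meta["model_id"],
            params=params,
            stderr=perr,
            window=tuple(json.loads(meta["window"])),
            n_points=int(meta["n_points"]),
            L0=float(meta["L0"]),
            residual_rms=float(meta["residual_rms"]),
            pair=tuple(pair) if pair else None,
            rho_i=rho_i,
            diagonal=meta.get("diagonal", "False") == "True",
        )
    if kind == "compressibility_table":
        err = data[:, 2]
        return CompressibilityTable(
            rho=data[:, 0], chi_inf=data[:, 1], kT=float(meta["kT"]),
            chi_err=None if np.all(np.isnan(err)) else err,
        )
    if kind == "kbi_table":
        return KBITable(
            xA=data[:, 0], rhoA=data[:, 1], rhoB=data[:, 2],
            G_AA=data[:, 3], G_AB=data[:, 4], G_BB=data[:, 5],
            kT=float(meta["kT"]),
        )
    if kind == "chempot_curve":
        ex = data[:, 2]
        err = data[:, 3]
        return ChemPotCurve(
            axis_name=meta["axis_name"],
            axis=data[:, 0],
            delta_mu=data[:, 1],
            kT=float(meta["kT"]),
            delta_mu_excess=None if np.all(np.isnan(ex)) else ex,
            stderr=None if np.all(np.isnan(err)) else err,
            reference=json.loads(meta.get("reference", "{}")),
        )
    raise ValueError(f"unrecognized table type {kind!r} in {path}")
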