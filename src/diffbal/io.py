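"""Matrix, system and trajectory serialization (CSV and JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .systems import (GoldbeterParameters, LinearSystem, NonlinearSystem,
                      Trajectory, goldbeter_system)

__all__ = [
    "save_matrix_csv", "load_matrix_csv",
    "save_matrix_json", "load_matrix_json",
    "save_matrix", "load_matrix",
    "save_system", "load_system",
    "save_trajectory_csv", "load_trajectory_csv",
]


def save_matrix_csv(path, M) -> None:
    """Row-major CSV, no header."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    np.savetxt(path, M, delimiter=",", fmt="%.17g")


def load_matrix_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", dtype=float))


def save_matrix_json(path, M) -> None:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    obj = {"rows": M.shape[0], "cols": M.shape[1], "data": M.tolist()}
    Path(path).write_text(json.dumps(obj))


def load_matrix_json(path) -> np.ndarray:
    obj = json.loads(Path(path).read_text())
    M = np.asarray(obj["data"], dtype=float)
    if M.shape != (obj["rows"], obj["cols"]):
        raise ValueError(f"matrix data shape {M.shape} does not match "
                         f"declared ({obj['rows']}, {obj['cols']})")
    return M


def save_matrix(path, M) -> None:
    path = Path(path)
    if path.suffix == ".json":
        save_matrix_json(path, M)
    else:
        save_matrix_csv(path, M)


def load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".json":
        return load_matrix_json(path)
    return load_matrix_csv(path)


def _resolve(entry, base: Path) -> np.ndarray:
    """A matrix field may be inline (list of lists) or a file reference."""
    if isinstance(entry, str):
        return load_matrix(base / entry)
    return np.asarray(entry, dtype=float)


def save_system(path, system, params: GoldbeterParameters | None = None) -> None:
    path = Path(path)
    if isinstance(system, LinearSystem):
        obj = {"type": "linear", "A": system.A.tolist(),
               "B": system.B.tolist(), "C": system.C.tolist()}
    elif isinstance(system, str) and system == "goldbeter":
        obj = {"type": "goldbeter",
               "params": dataclasses.asdict(params or GoldbeterParameters())}
    else:
        raise ValueError("only linear systems and the built-in 'goldbeter' "
                         "model are serializable")
    path.write_text(json.dumps(obj, indent=1))


def load_system(path):
    """Load a system spec.  Returns a LinearSystem, or a tuple
    (NonlinearSystem, GoldbeterParameters) for the built-in model."""
    path = Path(path)
    obj = json.loads(path.read_text())
    kind = obj.get("type")
    if kind == "linear":
        base = path.parent
        return LinearSystem(A=_resolve(obj["A"], base),
                            B=_resolve(obj["B"], base),
                            C=_resolve(obj["C"], base))
    if kind == "goldbeter":
        params = GoldbeterParameters(**obj.get("params", {}))
        return goldbeter_system(params), params
    raise ValueError(f"unsupported system type {kind!r} (custom systems must "
                     "be constructed programmatically)")


def save_trajectory_csv(path, traj: Trajectory) -> None:
    n = traj.states.shape[1]
    header = "t," + ",".join(f"x{i+1}" for i in range(n))
    data = np.column_stack([traj.times, traj.states])
    np.savetxt(path, data, delimiter=",", header=header, comments="")


def load_trajectory_csv(path) -> Trajectory:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return Trajectory(times=data[:, 0], states=data[:, 1:], input_u=0.0)
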