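"""File formats: parameter files, (extended) XYZ frames, trajectories, bias tables.

The force-field parameter file is flat ``key = value`` text with ``#``
comments; parsing is strict (every key required, unknown keys
rejected) so that a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from .potential import AtomicConfiguration, PotentialParameters
from .topology import BondTopology

__all__ = [
    "PARAM_KEYS",
    "read_params",
    "write_params",
    "params_from_dict",
    "read_xyz",
    "write_xyz",
    "read_trajectory",
    "write_trajectory",
    "read_bias",
    "write_bias",
]

PARAM_KEYS = (
    "H_OO", "H_OH", "H_HH",
    "eta_OO", "eta_OH", "eta_HH",
    "Z_O", "Z_H",
    "D_OO", "D_OH", "D_HH",
    "W_OO", "W_OH", "W_HH",
    "r1s", "r4s", "rc",
    "B_HOH", "xi", "r0", "cos_theta0",
)


def params_from_dict(values: dict) -> PotentialParameters:
    missing = set(PARAM_KEYS) - set(values)
    unknown = set(values) - set(PARAM_KEYS)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    v = {k: float(x) for k, x in values.items()}
    return PotentialParameters(
        H={"OO": v["H_OO"], "OH": v["H_OH"], "HH": v["H_HH"]},
        eta={"OO": v["eta_OO"], "OH": v["eta_OH"], "HH": v["eta_HH"]},
        Z={"O": v["Z_O"], "H": v["Z_H"]},
        D={"OO": v["D_OO"], "OH": v["D_OH"], "HH": v["D_HH"]},
        W={"OO": v["W_OO"], "OH": v["W_OH"], "HH": v["W_HH"]},
        r1s=v["r1s"], r4s=v["r4s"], rc=v["rc"],
        B=v["B_HOH"], xi=v["xi"], r0=v["r0"], cos_theta0=v["cos_theta0"],
    )


def read_params(path) -> PotentialParameters:
    """Read a flat key = value parameter file (strict schema)."""
    values = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key in values:
            raise ValueError(f"{path}:{lineno}: duplicate key {key!r}")
        values[key] = float(val.strip())
    return params_from_dict(values)


def write_params(path, params: PotentialParameters, header: str = "") -> None:
    v = {
        "H_OO": params.H["OO"], "H_OH": params.H["OH"], "H_HH": params.H["HH"],
        "eta_OO": params.eta["OO"], "eta_OH": params.eta["OH"], "eta_HH": params.eta["HH"],
        "Z_O": params.Z["O"], "Z_H": params.Z["H"],
        "D_OO": params.D["OO"], "D_OH": params.D["OH"], "D_HH": params.D["HH"],
        "W_OO": params.W["OO"], "W_OH": params.W["OH"], "W_HH": params.W["HH"],
        "r1s": params.r1s, "r4s": params.r4s, "rc": params.rc,
        "B_HOH": params.B, "xi": params.xi, "r0": params.r0,
        "cos_theta0": params.cos_theta0,
    }
    lines = [f"# {l}" for l in header.splitlines()] if header else []
    lines += [f"{k} = {v[k]!r}" for k in PARAM_KEYS]
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(path, config: AtomicConfiguration, comment: str = "", append: bool = False,
              topology: Optional[BondTopology] = None) -> None:
    """Write one XYZ frame; with a topology, a molecule-id column is added."""
    owner = topology.atom_owner if topology is not None else None
    lines = [str(config.n_atoms), comment.replace("\n", " ")]
    for i in range(config.n_atoms):
        x, y, z = config.positions[i]
        line = f"{config.species[i]} {x:.10f} {y:.10f} {z:.10f}"
        if owner is not None:
            line += f" {owner[i]}"
        lines.append(line)
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> list:
    """Read all frames of an XYZ file; returns a list of (config, comment)."""
    text = Path(path).read_text().splitlines()
    frames = []
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i].strip())
        comment = text[i + 1] if i + 1 < len(text) else ""
        species, positions = [], []
        for row in text[i + 2 : i + 2 + n]:
            parts = row.split()
            species.append(parts[0])
            positions.append([float(p) for p in parts[1:4]])
        frames.append((AtomicConfiguration(np.array(species), np.array(positions)), comment))
        i += 2 + n
    return frames


def write_trajectory(path, steps: np.ndarray, sizes: np.ndarray) -> None:
    """Two-column plain text: step index, cluster size."""
    np.savetxt(path, np.column_stack([steps, sizes]), fmt="%d", header="step n")


def read_trajectory(path) -> tuple:
    data = np.loadtxt(path, dtype=np.int64, ndmin=2)
    return data[:, 0], data[:, 1]


def write_bias(path, eta: np.ndarray, histogram: Optional[np.ndarray] = None) -> None:
    payload = {"eta": np.asarray(eta, dtype=float).tolist()}
    if histogram is not None:
        payload["histogram"] = np.asarray(histogram, dtype=float).tolist()
    Path(path).write_text(json.dumps(payload, indent=1))


def read_bias(path) -> tuple:
    payload = json.loads(Path(path).read_text())
    eta = np.asarray(payload["eta"], dtype=float)
    hist = np.asarray(payload.get("histogram", np.zeros_like(eta)), dtype=float)
    return eta, hist
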