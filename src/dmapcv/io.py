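"""File I/O: extended-XYZ trajectories, topology YAML, feature CSV.

The extended-XYZ dialect handled here is the minimal one the pipeline needs:
per-frame comment lines carrying whitespace-separated ``key=value`` tokens,
with the per-frame potential energy under the ``energy`` key.  Coordinates
are Angstrom; energy units follow the file and are echoed unchanged.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coordinates import FeatureSeries, ICTopology, Trajectory

__all__ = [
    "read_xyz",
    "write_xyz",
    "read_topology_yaml",
    "write_topology_yaml",
    "write_feature_csv",
    "read_feature_csv",
    "write_yaml",
    "read_yaml",
]


def _parse_comment(comment: str) -> dict[str, str]:
    out = {}
    for token in comment.split():
        if "=" in token:
            key, _, val = token.partition("=")
            out[key.lower()] = val.strip('"')
    return out


def read_xyz(path) -> Trajectory:
    """Read a (multi-frame) XYZ or extended-XYZ file.

    A per-frame energy is recovered from an ``energy=<float>`` token in the
    comment line when present on every frame.
    """
    lines = Path(path).read_text().splitlines()
    frames, energies, labels = [], [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        meta = _parse_comment(lines[i + 1])
        block = lines[i + 2 : i + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"truncated frame at line {i + 1} of {path}")
        symbols, coords = [], []
        for row in block:
            parts = row.split()
            symbols.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if labels is None:
            labels = symbols
        elif symbols != labels:
            raise ValueError("atom ordering changes between frames")
        frames.append(coords)
        energies.append(float(meta["energy"]) if "energy" in meta else None)
        i += 2 + n_atoms
    if not frames:
        raise ValueError(f"no frames found in {path}")
    has_energy = all(e is not None for e in energies)
    return Trajectory(
        frames=np.array(frames, dtype=float),
        energies=np.array(energies, dtype=float) if has_energy else None,
        element_labels=labels,
    )


def write_xyz(path, traj: Trajectory, comment_extra: str = "") -> None:
    """Write a trajectory as extended XYZ with ``energy=`` comment tokens."""
    labels = traj.element_labels or ["X"] * traj.n_atoms
    out = []
    for t in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        comment = f"frame={t}"
        if traj.energies is not None:
            comment += f" energy={traj.energies[t]:.12g}"
        if comment_extra:
            comment += " " + comment_extra
        out.append(comment)
        for sym, (x, y, z) in zip(labels, traj.frames[t]):
            out.append(f"{sym} {x:.10f} {y:.10f} {z:.10f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_topology_yaml(path) -> ICTopology:
    """Load an internal-coordinate topology (0-based indices) from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    return ICTopology(
        bonds=[tuple(b) for b in data.get("bonds", [])],
        angles=[tuple(a) for a in data.get("angles", [])],
        dihedrals=[tuple(d) for d in data.get("dihedrals", [])],
        names=data.get("names"),
    )


def write_topology_yaml(path, bonds=(), angles=(), dihedrals=(), names=None) -> None:
    data = {
        "bonds": [list(b) for b in bonds],
        "angles": [list(a) for a in angles],
        "dihedrals": [list(d) for d in dihedrals],
    }
    if names is not None:
        data["names"] = list(names)
    write_yaml(path, data)


def write_feature_csv(path, features: FeatureSeries) -> None:
    """One row per frame, header = coordinate names; angular flags in a comment row."""
    df = pd.DataFrame(features.values, columns=features.names)
    df.insert(0, "frame", np.arange(features.n_frames))
    with open(path, "w") as fh:
        fh.write("# is_angular: " + ",".join(str(int(v)) for v in features.is_angular) + "\n")
        df.to_csv(fh, index=False)


def read_feature_csv(path) -> FeatureSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# is_angular:"):
            raise ValueError("missing is_angular header comment")
        flags = np.array([int(v) for v in first.split(":", 1)[1].split(",")], dtype=bool)
        df = pd.read_csv(fh)
    df = df.drop(columns=["frame"])
    return FeatureSeries(values=df.to_numpy(float), is_angular=flags, names=list(df.columns))


def write_yaml(path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
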