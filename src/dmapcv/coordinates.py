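"""Cartesian-to-internal-coordinate conversion and geometric descriptors.

Everything downstream (diffusion maps, QSD monitoring, CV assessment,
committor solves) consumes either internal coordinates (bond lengths, bond
angles, dihedral angles) or rigid-body-aligned Cartesian coordinates produced
here.  Angles are stored in radians in ``(-pi, pi]`` throughout the package;
distances are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "ICTopology",
    "FeatureSeries",
    "DegenerateGeometryError",
    "compute_internal_coordinates",
    "wrap_angle",
    "wrap_angle_difference",
    "feature_distance",
    "pairwise_feature_distances",
    "kabsch_align",
    "coordination_number",
]

_TWO_PI = 2.0 * np.pi


class DegenerateGeometryError(ValueError):
    """An angle or dihedral is undefined because of (near-)collinear atoms."""


@dataclass
class Trajectory:
    """Ordered molecular snapshots of a single system.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, n_atoms, 3)``, Cartesian coordinates in
        Angstrom.
    energies:
        Optional per-frame potential energy; unit follows the input file and
        is echoed untouched in outputs.
    element_labels:
        Per-atom chemical symbols, length ``n_atoms``.
    dt:
        Time step between frames (fs); metadata only.
    temperature:
        Simulation temperature (K); metadata only.
    """

    frames: np.ndarray
    energies: np.ndarray | None = None
    element_labels: list[str] | None = None
    dt: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.shape != (self.n_frames,):
                raise ValueError("energies length must equal number of frames")
        if self.element_labels is not None and len(self.element_labels) != self.n_atoms:
            raise ValueError("element_labels length must equal number of atoms")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ICTopology:
    """Which internal coordinates to compute, by 0-based atom indices."""

    bonds: list[tuple[int, int]] = field(default_factory=list)
    angles: list[tuple[int, int, int]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.bonds = [tuple(b) for b in self.bonds]
        self.angles = [tuple(a) for a in self.angles]
        self.dihedrals = [tuple(d) for d in self.dihedrals]
        seen: set[tuple[int, ...]] = set()
        for entry in [*self.bonds, *self.angles, *self.dihedrals]:
            if len(set(entry)) != len(entry):
                raise ValueError(f"repeated atom index within entry {entry}")
            if entry in seen:
                raise ValueError(f"duplicate topology entry {entry}")
            seen.add(entry)
        if self.names is not None and len(self.names) != self.n_coordinates:
            raise ValueError("names length must equal total coordinate count")

    @property
    def n_coordinates(self) -> int:
        return len(self.bonds) + len(self.angles) + len(self.dihedrals)

    def validate_for(self, n_atoms: int) -> None:
        for entry in [*self.bonds, *self.angles, *self.dihedrals]:
            if any(i < 0 or i >= n_atoms for i in entry):
                raise IndexError(f"topology entry {entry} out of range for {n_atoms} atoms")

    def default_names(self, element_labels: list[str] | None = None) -> list[str]:
        def lab(i: int) -> str:
            if element_labels is not None:
                return f"{element_labels[i]}{i}"
            return str(i)

        names = []
        for b in self.bonds:
            names.append("-".join(lab(i) for i in b))
        for a in self.angles:
            names.append("-".join(lab(i) for i in a))
        for d in self.dihedrals:
            names.append("-".join(lab(i) for i in d))
        return names


@dataclass
class FeatureSeries:
    """Per-frame feature vectors with angular flags.

    ``values`` is ``(n_frames, d)``; ``is_angular[k]`` marks dimension ``k``
    as an angle/dihedral stored in radians in ``(-pi, pi]``; other dimensions
    are lengths in Angstrom.
    """

    values: np.ndarray
    is_angular: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_frames, d)")
        self.is_angular = np.asarray(self.is_angular, dtype=bool)
        if self.is_angular.shape != (self.values.shape[1],):
            raise ValueError("is_angular length must match feature dimension")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length must match feature dimension")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values: np.ndarray, is_angular=None, names=None) -> "FeatureSeries":
        values = np.atleast_2d(np.asarray(values, dtype=float))
        d = values.shape[1]
        if is_angular is None:
            is_angular = np.zeros(d, dtype=bool)
        if names is None:
            names = [f"x{k}" for k in range(d)]
        return cls(values=values, is_angular=np.asarray(is_angular, dtype=bool), names=list(names))


def wrap_angle(theta):
    """Reduce an angle (radians) to the repo-wide convention ``(-pi, pi]``."""
    theta = np.asarray(theta, dtype=float)
    wrapped = -((-theta + np.pi) % _TWO_PI - np.pi)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_angle_difference(theta1, theta2):
    """Minimal absolute angular separation of two angles, in ``[0, pi]``.

    A naive Euclidean difference of two angles near the branch cut (e.g.
    pi/6 versus 2 pi - pi/6) overstates their separation by up to 2 pi - 2x;
    the correct separation there is pi/3, obtained by reducing the difference
    modulo 2 pi and folding onto ``[0, pi]``.
    """
    d = np.abs(np.asarray(theta1, dtype=float) - np.asarray(theta2, dtype=float)) % _TWO_PI
    out = np.minimum(d, _TWO_PI - d)
    return out if out.ndim else float(out)


def feature_distance(a, b, is_angular=None) -> float:
    """Euclidean distance between two feature vectors with angular wrapping.

    Angular components contribute their wrapped difference (never exceeding
    pi); all other components contribute a plain difference.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if is_angular is None:
        is_angular = np.zeros(a.shape, dtype=bool)
    is_angular = np.asarray(is_angular, dtype=bool)
    diff = a - b
    if is_angular.any():
        diff = np.where(is_angular, wrap_angle_difference(a, b), diff)
    return float(np.linalg.norm(diff))


def pairwise_feature_distances(features: FeatureSeries | np.ndarray, is_angular=None) -> np.ndarray:
    """Full symmetric distance matrix under the wrapped-angle metric.

    Computed dimension-by-dimension so the angular wrap applies exactly;
    for the non-angular block this reduces to the ordinary Euclidean
    distance matrix.
    """
    if isinstance(features, FeatureSeries):
        X = features.values
        is_angular = features.is_angular
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if is_angular is None:
            is_angular = np.zeros(X.shape[1], dtype=bool)
        is_angular = np.asarray(is_angular, dtype=bool)
    n, d = X.shape
    sq = np.zeros((n, n))
    lin = ~is_angular
    if lin.any():
        Y = X[:, lin]
        # |y_i - y_j|^2 via the Gram expansion
        g = Y @ Y.T
        nrm = np.diag(g)
        sq += np.maximum(nrm[:, None] + nrm[None, :] - 2.0 * g, 0.0)
    for k in np.nonzero(is_angular)[0]:
        dd = np.abs(X[:, k][:, None] - X[:, k][None, :]) % _TWO_PI
        dd = np.minimum(dd, _TWO_PI - dd)
        sq += dd**2
    D = np.sqrt(sq)
    np.fill_diagonal(D, 0.0)
    return D


def _angle(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between row vectors v1, v2 in [0, pi] (atan2 form, stable)."""
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.einsum("...k,...k->...", v1, v2)
    return np.arctan2(cross, dot)


def compute_internal_coordinates(
    traj: Trajectory, topo: ICTopology, degenerate: str = "raise"
) -> FeatureSeries:
    """Bond lengths, bond angles and dihedral angles for every frame.

    Bond entries are Euclidean distances in Angstrom; angle entries are in
    ``[0, pi]``; dihedrals follow the IUPAC sign convention in ``(-pi, pi]``.

    ``degenerate`` controls what happens when collinear atoms make an angle
    or dihedral undefined: ``"raise"`` (default) raises
    :class:`DegenerateGeometryError` naming the frame and coordinate,
    ``"nan"`` stores NaN and emits a warning so downstream stages can drop
    the frame.
    """
    if degenerate not in ("raise", "nan"):
        raise ValueError("degenerate must be 'raise' or 'nan'")
    topo.validate_for(traj.n_atoms)
    X = traj.frames
    n = traj.n_frames
    cols: list[np.ndarray] = []
    names = topo.names or topo.default_names(traj.element_labels)
    tol = 1e-10

    def _flag(kind: str, name: str, bad_frames: np.ndarray, values: np.ndarray) -> np.ndarray:
        if bad_frames.size:
            msg = f"degenerate {kind} '{name}' (collinear atoms) in frame(s) {bad_frames[:5].tolist()}"
            if degenerate == "raise":
                raise DegenerateGeometryError(msg)
            warnings.warn(msg + "; storing NaN", RuntimeWarning, stacklevel=3)
            values = values.copy()
            values[bad_frames] = np.nan
        return values

    idx = 0
    for (i, j) in topo.bonds:
        cols.append(np.linalg.norm(X[:, j] - X[:, i], axis=1))
        idx += 1
    for (i, j, k) in topo.angles:
        v1 = X[:, i] - X[:, j]
        v2 = X[:, k] - X[:, j]
        norms = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        bad = np.nonzero(norms < tol)[0]
        cols.append(_flag("angle", names[idx], bad, _angle(v1, v2)))
        idx += 1
    for (i, j, k, l) in topo.dihedrals:
        b1 = X[:, j] - X[:, i]
        b2 = X[:, k] - X[:, j]
        b3 = X[:, l] - X[:, k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        norms = np.linalg.norm(n1, axis=1) * np.linalg.norm(n2, axis=1)
        bad = np.nonzero(norms < tol)[0]
        b2n = b2 / np.maximum(np.linalg.norm(b2, axis=1), tol)[:, None]
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", np.cross(n1, b2n), n2)
        phi = np.arctan2(y, x)
        # convention: phi in (-pi, pi], exact trans arrangement maps to +pi
        phi = np.where(np.isclose(phi, -np.pi), np.pi, phi)
        cols.append(_flag("dihedral", names[idx], bad, phi))
        idx += 1

    values = np.column_stack(cols) if cols else np.empty((n, 0))
    is_angular = np.array(
        [False] * len(topo.bonds) + [True] * (len(topo.angles) + len(topo.dihedrals))
    )
    return FeatureSeries(values=values, is_angular=is_angular, names=list(names))


def kabsch_align(traj: Trajectory, reference: np.ndarray) -> tuple[Trajectory, np.ndarray]:
    """Rigid-body superposition of every frame onto a reference frame.

    Each frame is translated to the reference centroid and rotated by the
    optimal (Kabsch) rotation; the per-frame RMSD after superposition is
    returned alongside the aligned trajectory.  With fewer than three
    non-collinear atoms the rotation is ill-posed: a warning is emitted and
    only the translation is applied.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_atoms, 3):
        raise ValueError("reference must match trajectory atom count")
    ref_c = reference - reference.mean(axis=0)
    # rank of the centered reference decides whether a rotation is defined
    well_posed = traj.n_atoms >= 3 and np.linalg.matrix_rank(ref_c, tol=1e-10) >= 2
    if not well_posed:
        warnings.warn(
            "alignment ill-posed (fewer than 3 non-collinear atoms); "
            "applying translation only",
            RuntimeWarning,
            stacklevel=2,
        )
    aligned = np.empty_like(traj.frames)
    rmsd = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        frame_c = traj.frames[t] - traj.frames[t].mean(axis=0)
        if well_posed:
            rot, _ = Rotation.align_vectors(ref_c, frame_c)
            frame_c = rot.apply(frame_c)
        aligned[t] = frame_c + reference.mean(axis=0)
        rmsd[t] = np.sqrt(np.mean(np.sum((frame_c - ref_c) ** 2, axis=1)))
    out = Trajectory(
        frames=aligned,
        energies=None if traj.energies is None else traj.energies.copy(),
        element_labels=traj.element_labels,
        dt=traj.dt,
        temperature=traj.temperature,
    )
    return out, rmsd


def coordination_number(
    frame: np.ndarray,
    center: int,
    neighbors: list[tuple[int, float]],
    steepness: float = 10.0,
) -> float:
    """Smooth neighbor count of one atom via Fermi-Dirac switching functions.

    ``CN = sum_j 1 / (1 + exp(kappa * (r_j - r0_j)))`` over the listed
    neighbors, where ``r_j`` is the center-neighbor distance and ``r0_j`` the
    corresponding equilibrium distance.  Each term tends to 1 well inside
    ``r0_j`` and to 0 well outside, so ``CN`` smoothly counts neighbors near
    their equilibrium positions; it is bounded by the neighbor count and
    equals half-integer contributions exactly at ``r_j = r0_j``.

    ``steepness`` (kappa, 1/Angstrom, default 10) sets the switch width.
    """
    frame = np.asarray(frame, dtype=float)
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    total = 0.0
    for j, r0 in neighbors:
        if j == center:
            raise ValueError("center atom listed among its own neighbors")
        if r0 <= 0:
            raise ValueError("equilibrium distance r0 must be positive")
        r = float(np.linalg.norm(frame[j] - frame[center]))
        # guard against overflow for distant neighbors
        z = steepness * (r - r0)
        total += 1.0 / (1.0 + np.exp(min(z, 700.0)))
    return total
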