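"""Synthetic systems with known answers: Langevin samplers and oracles.

Every statistical structure the analysis assumes is generated here with an
independent ground truth attached: overdamped Langevin trajectories on
analytic potentials, a closed-form 1-D committor by quadrature, an empirical
shooting committor, and a finite-difference discretization of the backward
Kolmogorov operator whose spectrum checks the diffusion-map generator.  None
of these code paths touch the diffusion-map modules.

Provided systems
----------------
double_well_1d   U(x) = h (x^2 - 1)^2, minima at +-1, barrier h at 0.
two_well_2d      U(x, y) = h (x^2 - 1)^2 + (kappa/2) y^2; x is the slow
                 coordinate by construction (transverse stiffness kappa is
                 much larger than the basin curvature 8h).
ou_1d            U(x) = (k/2) x^2; generator spectrum lambda_j = -j k.
toy_triatomic    three atoms (H, O, O) described by internal coordinates
                 (r1, r2, theta): double well in the reactive bond r1,
                 harmonic in the spectator bond r2 and in the bend theta,
                 with an index-1 saddle at the r1 barrier.  Mimics the
                 association topology H + O2 -> HO2 (two bonds + one angle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.integrate
import scipy.linalg

from .coordinates import Trajectory

__all__ = [
    "SyntheticSystem",
    "LangevinResult",
    "double_well_1d",
    "two_well_2d",
    "ou_1d",
    "toy_triatomic",
    "simulate_langevin",
    "barrier_shooting_ensemble",
    "analytic_committor_1d",
    "empirical_committor",
    "fd_generator_1d",
    "fd_committor_1d",
    "make_fixture_set",
]


@dataclass
class SyntheticSystem:
    """An analytic potential with named reference configurations.

    ``references`` holds at least "reactant", "product" and (for bistable
    systems) "barrier"; each is a stationary point of ``U``.  Optional extras
    carry the oracle structure: ``generator_spectrum(j)`` for systems with a
    closed-form Kolmogorov spectrum, ``to_cartesian`` for the triatomic's
    Z-matrix-style embedding, ``ic_names``/``is_angular`` describing the
    coordinate vector.
    """

    name: str
    dimension: int
    potential: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    beta: float
    references: dict[str, np.ndarray] = field(default_factory=dict)
    generator_spectrum: Callable[[int], float] | None = None
    to_cartesian: Callable[[np.ndarray], np.ndarray] | None = None
    element_labels: list[str] | None = None
    ic_names: list[str] | None = None
    is_angular: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.potential(x) for x in X])


@dataclass
class LangevinResult:
    """Positions and per-frame energies from one Euler-Maruyama run."""

    positions: np.ndarray  # (n_frames, dimension)
    energies: np.ndarray
    dt: float
    beta: float
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


def double_well_1d(h: float = 5.0, beta: float = 3.0) -> SyntheticSystem:
    """Symmetric quartic double well ``U(x) = h (x^2 - 1)^2``."""

    def U(x):
        x = np.asarray(x, dtype=float).reshape(-1)[0]
        return h * (x * x - 1.0) ** 2

    def gradU(x):
        x = np.asarray(x, dtype=float)  # batch-safe: elementwise on last axis
        return 4.0 * h * x * (x * x - 1.0)

    return SyntheticSystem(
        name="double_well_1d",
        dimension=1,
        potential=U,
        gradient=gradU,
        beta=beta,
        references={
            "reactant": np.array([-1.0]),
            "product": np.array([1.0]),
            "barrier": np.array([0.0]),
        },
        params={"h": h},
    )


def two_well_2d(h: float = 5.0, kappa: float = 200.0, beta: float = 3.0) -> SyntheticSystem:
    """Double well in x, stiff harmonic channel in y; slow CV is x."""

    def U(z):
        x, y = np.asarray(z, dtype=float).reshape(2)
        return h * (x * x - 1.0) ** 2 + 0.5 * kappa * y * y

    def gradU(z):
        z = np.asarray(z, dtype=float)  # batch-safe: acts on the last axis
        x, y = z[..., 0], z[..., 1]
        return np.stack([4.0 * h * x * (x * x - 1.0), kappa * y], axis=-1)

    return SyntheticSystem(
        name="two_well_2d",
        dimension=2,
        potential=U,
        gradient=gradU,
        beta=beta,
        references={
            "reactant": np.array([-1.0, 0.0]),
            "product": np.array([1.0, 0.0]),
            "barrier": np.array([0.0, 0.0]),
        },
        params={"h": h, "kappa": kappa},
    )


def ou_1d(k: float = 2.0, beta: float = 1.0) -> SyntheticSystem:
    """Ornstein-Uhlenbeck process; Kolmogorov spectrum ``lambda_j = -j k``."""

    def U(x):
        x = np.asarray(x, dtype=float).reshape(-1)[0]
        return 0.5 * k * x * x

    def gradU(x):
        return k * np.asarray(x, dtype=float)

    return SyntheticSystem(
        name="ou_1d",
        dimension=1,
        potential=U,
        gradient=gradU,
        beta=beta,
        references={"reactant": np.array([0.0])},
        generator_spectrum=lambda j: -float(j) * k,
        params={"k": k},
    )


def toy_triatomic(
    h: float = 5.0,
    r1_center: float = 1.6,
    r1_halfwidth: float = 0.45,
    r2_eq: float = 1.25,
    k2: float = 60.0,
    theta_eq: float = 1.85,
    ktheta: float = 30.0,
    beta: float = 3.0,
) -> SyntheticSystem:
    """Triatomic (H, O1, O2) in internal coordinates ``(r1, r2, theta)``.

    ``r1`` (H-O1, the reactive bond) sits in a quartic double well with
    minima at ``r1_center +- r1_halfwidth`` — bound (product) versus
    stretched (reactant) — while the spectator O1-O2 bond ``r2`` and the
    H-O1-O2 bend ``theta`` are harmonic.  The barrier configuration
    ``(r1_center, r2_eq, theta_eq)`` is an index-1 saddle: a maximum along
    r1 and a minimum along r2 and theta.
    """
    a2 = r1_halfwidth**2

    def U(z):
        r1, r2, th = np.asarray(z, dtype=float).reshape(3)
        return (
            h / a2**2 * ((r1 - r1_center) ** 2 - a2) ** 2
            + 0.5 * k2 * (r2 - r2_eq) ** 2
            + 0.5 * ktheta * (th - theta_eq) ** 2
        )

    def gradU(z):
        z = np.asarray(z, dtype=float)  # batch-safe: acts on the last axis
        u = z[..., 0] - r1_center
        return np.stack(
            [
                4.0 * h / a2**2 * u * (u * u - a2),
                k2 * (z[..., 1] - r2_eq),
                ktheta * (z[..., 2] - theta_eq),
            ],
            axis=-1,
        )

    def to_cartesian(z):
        """Z-matrix placement: O1 at origin, H along +x at r1, O2 in-plane."""
        r1, r2, th = np.asarray(z, dtype=float).reshape(3)
        return np.array(
            [
                [r1, 0.0, 0.0],  # H
                [0.0, 0.0, 0.0],  # O1
                [r2 * np.cos(th), r2 * np.sin(th), 0.0],  # O2
            ]
        )

    return SyntheticSystem(
        name="toy_triatomic",
        dimension=3,
        potential=U,
        gradient=gradU,
        beta=beta,
        references={
            "reactant": np.array([r1_center + r1_halfwidth, r2_eq, theta_eq]),
            "product": np.array([r1_center - r1_halfwidth, r2_eq, theta_eq]),
            "barrier": np.array([r1_center, r2_eq, theta_eq]),
        },
        to_cartesian=to_cartesian,
        element_labels=["H", "O", "O"],
        ic_names=["H-O1", "O1-O2", "H-O1-O2"],
        is_angular=np.array([False, False, True]),
        params={
            "h": h,
            "r1_center": r1_center,
            "r1_halfwidth": r1_halfwidth,
            "r2_eq": r2_eq,
            "k2": k2,
            "theta_eq": theta_eq,
            "ktheta": ktheta,
        },
    )


def simulate_langevin(
    system: SyntheticSystem,
    x0: np.ndarray,
    dt: float = 1e-3,
    n_steps: int = 4000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    stride: int = 1,
    include_initial: bool = True,
    curvature_hint: float | None = None,
) -> LangevinResult:
    """Euler-Maruyama integration of overdamped Langevin dynamics.

    ``x_{t+1} = x_t - grad U(x_t) dt + sqrt(2 dt / beta) xi_t`` with standard
    normal ``xi_t``.  Every ``stride``-th configuration is recorded (plus the
    initial one unless ``include_initial=False``); per-frame potential
    energies are stored alongside.  ``noise=False`` disables the stochastic
    term (deterministic gradient descent), useful as a zero-temperature
    limit.  A blow-up (non-finite state) raises, naming the step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if curvature_hint is not None and dt * curvature_hint > 1.0:
        warnings.warn(
            f"dt={dt} exceeds the stability bound 1/curvature ~ {1.0 / curvature_hint:.2e}; "
            "expect unstable integration",
            RuntimeWarning,
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).reshape(system.dimension).copy()
    amp = np.sqrt(2.0 * dt / system.beta)
    frames = []
    energies = []
    if include_initial:
        frames.append(x.copy())
        energies.append(system.potential(x))
    for step in range(1, n_steps + 1):
        x = x - system.gradient(x) * dt
        if noise:
            x = x + amp * rng.standard_normal(system.dimension)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(f"Langevin integration blew up at step {step}")
        if step % stride == 0:
            frames.append(x.copy())
            energies.append(system.potential(x))
    return LangevinResult(
        positions=np.array(frames), energies=np.array(energies), dt=dt, beta=system.beta, seed=seed
    )


def barrier_shooting_ensemble(
    system: SyntheticSystem,
    n_runs: int = 60,
    n_steps: int = 67,
    dt: float = 1e-3,
    seed: int | None = None,
    start: str = "barrier",
) -> LangevinResult:
    """Concatenated short Langevin runs launched from the transition state.

    Emulates trajectory ensembles initiated at a saddle point spanning both
    product and reactant basins.  The shared starting configuration is
    recorded once (frame 0); each run then contributes its ``n_steps``
    post-launch frames, so duplicated snapshots never enter the kernel.

    The default shape (60 runs x 67 steps, ~4000 frames) favors many short
    runs: committor estimates at the launch point average over independent
    barrier passages, and their spread scales with the inverse square root
    of the run count, not the frame count.  Runs must still be long enough
    to populate the basin neighborhoods the committor solve clamps.
    """
    rng = np.random.default_rng(seed)
    x0 = system.references[start]
    chunks = [np.asarray(x0, dtype=float).reshape(1, system.dimension)]
    energy_chunks = [np.array([system.potential(x0)])]
    for _ in range(n_runs):
        res = simulate_langevin(
            system, x0, dt=dt, n_steps=n_steps, rng=rng, include_initial=False
        )
        chunks.append(res.positions)
        energy_chunks.append(res.energies)
    return LangevinResult(
        positions=np.concatenate(chunks),
        energies=np.concatenate(energy_chunks),
        dt=dt,
        beta=system.beta,
        seed=seed,
    )


def find_hopping_run(
    system: SyntheticSystem | None = None,
    seed_start: int = 0,
    n_steps: int = 4000,
    dt: float = 1e-3,
    hop_window: tuple[int, int] = (1800, 3200),
    confinement: float = 0.1,
    hop_level: float = 0.5,
    max_seeds: int = 500,
) -> tuple[LangevinResult, int, int]:
    """Seed-select a double-well run that cleanly hops at a known step.

    Scans seeds from ``seed_start`` for a trajectory that (a) stays confined
    below ``confinement`` in the reactive coordinate until shortly before its
    first crossing of ``hop_level`` and (b) hops within ``hop_window``.  The
    hop step is located by direct basin labeling of the trajectory, giving a
    ground truth for change-point detectors.  Returns ``(run, hop_step,
    seed)``.  The default system is the low-barrier double well (h=1,
    beta=1), where hops occur within a few thousand steps.
    """
    if system is None:
        system = double_well_1d(h=1.0, beta=1.0)
    for seed in range(seed_start, seed_start + max_seeds):
        res = simulate_langevin(
            system,
            system.references["reactant"],
            dt=dt,
            n_steps=n_steps,
            seed=seed,
            include_initial=False,
        )
        x = res.positions[:, 0]
        cross = np.nonzero(x > hop_level)[0]
        if not len(cross):
            continue
        hop = int(cross[0])
        if not hop_window[0] <= hop <= hop_window[1]:
            continue
        if x[: hop - 100].max() >= confinement:
            continue
        return res, hop, seed
    raise RuntimeError(f"no clean hopping run found in {max_seeds} seeds from {seed_start}")


def analytic_committor_1d(
    system: SyntheticSystem, a: float, b: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Closed-form 1-D committor by quadrature.

    For ``L q = 0`` with ``q(a) = 0, q(b) = 1`` the solution is
    ``q(x) = int_a^x exp(beta U) ds / int_a^b exp(beta U) ds``.  The
    exponent is shifted by its maximum over [a, b] before integration so
    steep barriers do not overflow; integrals use adaptive quadrature.
    """
    if system.dimension != 1:
        raise ValueError("analytic committor requires a 1-D system")
    if not a < b:
        raise ValueError("need a < b")
    grid = np.linspace(a, b, 2001)
    umax = max(system.potential(np.array([s])) for s in grid)

    def integrand(s):
        return np.exp(system.beta * (system.potential(np.array([s])) - umax))

    denom, _ = scipy.integrate.quad(integrand, a, b, limit=200)

    def q(x):
        x = np.atleast_1d(np.asarray(x, dtype=float)).reshape(-1)
        out = np.empty(x.shape)
        for i, xi in enumerate(x):
            if xi <= a:
                out[i] = 0.0
            elif xi >= b:
                out[i] = 1.0
            else:
                num, _ = scipy.integrate.quad(integrand, a, xi, limit=200)
                out[i] = num / denom
        return out if out.size > 1 else float(out[0])

    return q


def empirical_committor(
    system: SyntheticSystem,
    points: np.ndarray,
    n_shots: int,
    a_region: tuple[np.ndarray, float],
    b_region: tuple[np.ndarray, float],
    dt: float = 1e-3,
    seed: int | None = None,
    max_steps: int = 200_000,
) -> dict[str, np.ndarray]:
    """Shooting estimate of the committor: fraction of runs hitting B first.

    ``a_region``/``b_region`` are ``(center, radius)`` balls.  Returns the
    per-point hit fraction among decided shots, its binomial standard error,
    and the count of undecided shots (runs exceeding ``max_steps`` without
    hitting either region), which are reported rather than silently folded
    into either outcome.
    """
    (ca, ra), (cb, rb) = a_region, b_region
    ca = np.asarray(ca, dtype=float).reshape(system.dimension)
    cb = np.asarray(cb, dtype=float).reshape(system.dimension)
    if np.linalg.norm(ca - cb) <= ra + rb:
        raise ValueError("A and B regions overlap")
    if n_shots < 1:
        raise ValueError("n_shots must be >= 1")
    rng = np.random.default_rng(seed)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    amp = np.sqrt(2.0 * dt / system.beta)
    q = np.empty(len(pts))
    se = np.empty(len(pts))
    undecided = np.zeros(len(pts), dtype=int)
    for i, p in enumerate(pts):
        # propagate all shots for this point in lockstep (batched gradient)
        x = np.tile(p, (n_shots, 1))
        alive = np.ones(n_shots, dtype=bool)
        hits_b = 0
        decided = 0
        for _ in range(max_steps):
            xa = x[alive]
            xa = xa - system.gradient(xa) * dt + amp * rng.standard_normal(xa.shape)
            in_a = np.linalg.norm(xa - ca, axis=1) <= ra
            in_b = np.linalg.norm(xa - cb, axis=1) <= rb
            done = in_a | in_b
            decided += int(done.sum())
            hits_b += int(in_b.sum())
            x[alive] = xa
            idx = np.nonzero(alive)[0]
            alive[idx[done]] = False
            if not alive.any():
                break
        undecided[i] = int(alive.sum())
        if decided == 0:
            q[i] = np.nan
            se[i] = np.nan
        else:
            q[i] = hits_b / decided
            # Agresti-Coull-shrunk proportion keeps the error bar meaningful
            # at observed fractions of exactly 0 or 1
            qt = (hits_b + 1.0) / (decided + 2.0)
            se[i] = np.sqrt(qt * (1.0 - qt) / decided)
    return {"q": q, "stderr": se, "undecided": undecided}


def fd_generator_1d(
    system: SyntheticSystem, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-difference discretization of ``L = -U' d/dx + beta^-1 d2/dx2``.

    Reflecting (zero-derivative) boundaries via ghost nodes.  Returns the
    dense generator matrix and its eigenpairs sorted by descending real part,
    so index 0 is the null mode (eigenvalue 0, constant eigenfunction).
    """
    x = np.asarray(grid, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("grid too coarse")
    hs = np.diff(x)
    if not np.allclose(hs, hs[0], rtol=1e-8):
        raise ValueError("grid must be uniform")
    h = hs[0]
    binv = 1.0 / system.beta
    dU = np.array([system.gradient(np.array([xi]))[0] for xi in x])
    L = np.zeros((n, n))
    for i in range(n):
        if i == 0:
            # ghost node x_{-1} with f(-1)=f(1): drift term vanishes
            L[0, 0] = -2.0 * binv / h**2
            L[0, 1] = 2.0 * binv / h**2
        elif i == n - 1:
            L[i, i] = -2.0 * binv / h**2
            L[i, i - 1] = 2.0 * binv / h**2
        else:
            L[i, i - 1] = binv / h**2 + dU[i] / (2 * h)
            L[i, i] = -2.0 * binv / h**2
            L[i, i + 1] = binv / h**2 - dU[i] / (2 * h)
    vals, vecs = scipy.linalg.eig(L)
    order = np.argsort(-vals.real)
    vals = vals[order].real
    vecs = vecs[:, order].real
    # convergence sanity: spectrum of a reflecting generator is nonpositive
    if vals[0] > 1e-6:
        raise ValueError("grid too coarse: spurious positive eigenvalue")
    return L, vals, vecs


def fd_committor_1d(
    system: SyntheticSystem, grid: np.ndarray, a: float, b: float
) -> tuple[np.ndarray, np.ndarray]:
    """Committor on a grid by solving the discrete boundary-value problem.

    Dirichlet conditions ``q = 0`` left of (and at) ``a`` and ``q = 1`` right
    of (and at) ``b`` on the finite-difference generator.  Independent of the
    diffusion-map code path; used as an oracle.
    """
    L, _, _ = fd_generator_1d(system, grid)
    x = np.asarray(grid, dtype=float)
    q = np.zeros(len(x))
    in_b = x >= b
    in_a = x <= a
    interior = ~(in_a | in_b)
    q[in_b] = 1.0
    Lcc = L[np.ix_(interior, interior)]
    rhs = -L[np.ix_(interior, in_b)].sum(axis=1)
    q[interior] = scipy.linalg.solve(Lcc, rhs)
    return x, q


def _basin_label(positions: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label frames by the sign of the reactive coordinate: -1, 0 (barrier region), +1."""
    c = np.atleast_2d(positions)[:, 0]
    return np.where(c > threshold, 1, np.where(c < -threshold, -1, 0))


def make_fixture_set(path, seed: int = 0) -> dict:
    """Write a deterministic on-disk fixture bundle for the toy triatomic.

    Produces extended-XYZ trajectories (a basin-confined run for local maps /
    QSD checks and a barrier-initiated shooting ensemble for global maps /
    committors), reactant/product/transition-state reference XYZ files, an
    internal-coordinate topology YAML, and a manifest recording every
    generation parameter.  Identical seeds give byte-identical bundles.
    """
    from pathlib import Path

    from . import io as dio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    system = toy_triatomic()
    dt, n_basin = 1e-3, 2000
    basin = simulate_langevin(
        system, system.references["product"], dt=dt, n_steps=n_basin, seed=seed
    )
    shoot = barrier_shooting_ensemble(
        system, n_runs=20, n_steps=200, dt=dt, seed=seed + 1
    )

    def as_traj(res: LangevinResult) -> Trajectory:
        frames = np.array([system.to_cartesian(z) for z in res.positions])
        return Trajectory(
            frames=frames, energies=res.energies, element_labels=system.element_labels
        )

    files = {
        "basin_trajectory": path / "basin.extxyz",
        "barrier_ensemble": path / "barrier_ensemble.extxyz",
        "reactant": path / "reactant.xyz",
        "product": path / "product.xyz",
        "transition_state": path / "transition_state.xyz",
        "topology": path / "topology.yaml",
        "manifest": path / "manifest.yaml",
    }
    dio.write_xyz(files["basin_trajectory"], as_traj(basin))
    dio.write_xyz(files["barrier_ensemble"], as_traj(shoot))
    for key in ("reactant", "product", "transition_state"):
        ref = system.references["barrier" if key == "transition_state" else key]
        frame = system.to_cartesian(ref)
        dio.write_xyz(
            files[key],
            Trajectory(
                frames=frame[None, :, :],
                energies=np.array([system.potential(ref)]),
                element_labels=system.element_labels,
            ),
        )
    dio.write_topology_yaml(
        files["topology"],
        bonds=[(0, 1), (1, 2)],
        angles=[(0, 1, 2)],
        names=system.ic_names,
    )
    manifest = {
        "system": system.name,
        "parameters": {k: float(v) for k, v in system.params.items()},
        "beta": float(system.beta),
        "dt": dt,
        "basin_steps": n_basin,
        "shooting": {"n_runs": 20, "n_steps": 200},
        "seed": int(seed),
        "files": {k: v.name for k, v in files.items()},
    }
    dio.write_yaml(files["manifest"], manifest)
    return {k: str(v) for k, v in files.items()}
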