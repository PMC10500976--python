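"""Discrete committor functions on diffusion-map graphs.

Given snapshots with designated reactant (A) and product (B) index sets, the
committor ``q_i`` — the probability that overdamped Langevin dynamics started
at snapshot ``i`` reaches B before A — is approximated by solving the
discrete boundary-value problem on the diffusion-map generator: ``(L q)_c =
0`` on the complement ``c`` of ``A u B`` with ``q = 0`` on A and ``q = 1`` on
B.  Because ``L`` and ``P - I`` differ by a positive scale, the system is
solved on transition-matrix rows: ``(I - P_cc) q_c = P_cB 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .coordinates import FeatureSeries, feature_distance
from .dmap import DiffusionMapModel

__all__ = [
    "BasinSpec",
    "CommittorSolution",
    "define_basins",
    "solve_committor",
    "isocommittor_band",
    "committor_validation",
]


@dataclass
class BasinSpec:
    """Result of assigning frames to a reference-centered basin."""

    reference: np.ndarray
    cutoff: float
    indices: np.ndarray


@dataclass
class CommittorSolution:
    """Per-snapshot committor values with the basins that produced them.

    ``q`` is exactly 0 on A and 1 on B; interior values obey the discrete
    maximum principle (within solver round-off) for connected kernel graphs.
    ``residual`` is the infinity norm of ``(P - I) q`` over interior rows.
    """

    q: np.ndarray
    basin_a: BasinSpec
    basin_b: BasinSpec
    residual: float


def define_basins(
    features: FeatureSeries | np.ndarray,
    reactant_ref: np.ndarray,
    product_ref: np.ndarray,
    cutoff: float,
    is_angular: np.ndarray | None = None,
) -> tuple[BasinSpec, BasinSpec]:
    """Assign frames within ``cutoff`` of each reference to its basin.

    Distances use the wrapped-angle feature metric.  A frame within the
    cutoff of both references goes to the nearer one, so A and B are always
    disjoint.  An empty basin raises with a hint to enlarge the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if isinstance(features, FeatureSeries):
        X = features.values
        is_angular = features.is_angular
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    ra = np.asarray(reactant_ref, dtype=float).reshape(-1)
    rb = np.asarray(product_ref, dtype=float).reshape(-1)
    da = np.array([feature_distance(x, ra, is_angular) for x in X])
    db = np.array([feature_distance(x, rb, is_angular) for x in X])
    in_a = (da <= cutoff) & (da <= db)
    in_b = (db <= cutoff) & (db < da)
    for name, mask in (("reactant (A)", in_a), ("product (B)", in_b)):
        if not mask.any():
            raise ValueError(f"no frames within cutoff {cutoff} of the {name} reference; "
                             "increase the cutoff or check the reference")
    if in_a.all() or in_b.all():
        raise ValueError("basins cover every frame; decrease the cutoff")
    return (
        BasinSpec(reference=ra, cutoff=cutoff, indices=np.nonzero(in_a)[0]),
        BasinSpec(reference=rb, cutoff=cutoff, indices=np.nonzero(in_b)[0]),
    )


def _check_connected(K: np.ndarray) -> None:
    # treat kernel entries below round-off as absent edges
    thresh = max(K.max() * 1e-12, 1e-300)
    n_comp, labels = connected_components((K > thresh).astype(np.int8), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"kernel graph is disconnected ({n_comp} components, sizes {sizes.tolist()}); "
            "the committor system is singular — increase the kernel bandwidth"
        )


def solve_committor(
    model: DiffusionMapModel, A: BasinSpec | np.ndarray, B: BasinSpec | np.ndarray
) -> CommittorSolution:
    """Solve the discrete committor boundary-value problem on the model's graph."""
    a_idx = np.asarray(A.indices if isinstance(A, BasinSpec) else A, dtype=int)
    b_idx = np.asarray(B.indices if isinstance(B, BasinSpec) else B, dtype=int)
    if a_idx.size == 0 or b_idx.size == 0:
        raise ValueError("both basins must be nonempty")
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("A and B overlap")
    n = model.n_samples
    interior = np.setdiff1d(np.arange(n), np.union1d(a_idx, b_idx))
    if interior.size == 0:
        raise ValueError("no interior snapshots between the basins")
    _check_connected(model.kernel_matrix)
    P = model.transition_matrix
    q = np.zeros(n)
    q[b_idx] = 1.0
    M = np.eye(interior.size) - P[np.ix_(interior, interior)]
    rhs = P[np.ix_(interior, b_idx)].sum(axis=1)
    q[interior] = scipy.linalg.solve(M, rhs)
    residual = float(np.max(np.abs((P @ q - q)[interior])))
    basin_a = A if isinstance(A, BasinSpec) else BasinSpec(np.array([]), np.nan, a_idx)
    basin_b = B if isinstance(B, BasinSpec) else BasinSpec(np.array([]), np.nan, b_idx)
    return CommittorSolution(q=q, basin_a=basin_a, basin_b=basin_b, residual=residual)


def isocommittor_band(
    solution: CommittorSolution | np.ndarray, level: float = 0.5, tol: float = 0.05
) -> np.ndarray:
    """Snapshot indices with ``|q - level| <= tol`` (the transition region)."""
    q = solution.q if isinstance(solution, CommittorSolution) else np.asarray(solution, float)
    return np.nonzero(np.abs(q - level) <= tol)[0]


def committor_validation(
    solution: CommittorSolution, oracle_q: np.ndarray, interior_only: bool = True
) -> dict[str, float]:
    """RMSE and max absolute error of the solved committor against an oracle."""
    oracle_q = np.asarray(oracle_q, dtype=float).reshape(-1)
    if oracle_q.shape != solution.q.shape:
        raise ValueError("oracle length mismatch")
    if interior_only:
        mask = np.ones(len(oracle_q), dtype=bool)
        mask[solution.basin_a.indices] = False
        mask[solution.basin_b.indices] = False
    else:
        mask = np.ones(len(oracle_q), dtype=bool)
    err = solution.q[mask] - oracle_q[mask]
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "max_error": float(np.max(np.abs(err))),
        "n_interior": int(mask.sum()),
    }
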