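"""Potential-energy and free-energy surfaces in collective-variable planes.

A candidate CV pair is validated geometrically: anchor a 2-D grid at the
transition-state configuration ``z_ts``, step along two direction vectors
``u1, u2`` (standard basis columns for internal-coordinate CVs, principal
components for PCA CVs), evaluate the potential energy at each node, and
classify the anchored node.  An index-1 saddle at the anchor means the CV
pair resolves the barrier; no saddle means the pair hides the reaction.

The free-energy estimator here is a plain 2-D histogram Boltzmann inversion
``F = -log(rho)/beta`` — a deliberately simple stand-in estimator, flagged as
such in its output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSurface",
    "project_grid",
    "evaluate_surface",
    "classify_stationary_point",
    "free_energy_surface",
]


@dataclass
class GridSurface:
    """A rectangular CV-plane grid with (optionally) energies at each node.

    ``nodes[i, j]`` is the full configuration at displacement
    ``(c1[i], c2[j])`` from the anchor; ``energies[i, j]`` is filled by
    :func:`evaluate_surface`.
    """

    c1: np.ndarray
    c2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    anchor: np.ndarray
    nodes: np.ndarray
    energies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def anchor_node(self) -> tuple[int, int]:
        """Grid indices of the node closest to zero displacement."""
        return int(np.argmin(np.abs(self.c1))), int(np.argmin(np.abs(self.c2)))


def project_grid(
    z_ts: np.ndarray,
    u1: np.ndarray,
    u2: np.ndarray,
    bounds: tuple[float, float, float, float],
    n1: int = 21,
    n2: int = 21,
) -> GridSurface:
    """Uniform grid of configurations ``z_ts + c1 u1 + c2 u2``.

    ``bounds = (c1_lb, c1_ub, c2_lb, c2_ub)``.  For the anchored node to lie
    exactly on the grid, include 0 in both ranges (odd counts with symmetric
    bounds do).  Directions must be linearly independent.
    """
    z_ts = np.asarray(z_ts, dtype=float).reshape(-1)
    u1 = np.asarray(u1, dtype=float).reshape(-1)
    u2 = np.asarray(u2, dtype=float).reshape(-1)
    if u1.shape != z_ts.shape or u2.shape != z_ts.shape:
        raise ValueError("direction vectors must match the configuration dimension")
    if np.linalg.matrix_rank(np.column_stack([u1, u2]), tol=1e-12) < 2:
        raise ValueError("direction vectors are linearly dependent")
    c1lb, c1ub, c2lb, c2ub = bounds
    if not (c1lb < c1ub and c2lb < c2ub):
        raise ValueError("bounds must satisfy lb < ub on both axes")
    c1 = np.linspace(c1lb, c1ub, n1)
    c2 = np.linspace(c2lb, c2ub, n2)
    nodes = z_ts[None, None, :] + c1[:, None, None] * u1[None, None, :] + c2[None, :, None] * u2[None, None, :]
    return GridSurface(c1=c1, c2=c2, u1=u1, u2=u2, anchor=z_ts, nodes=nodes)


def evaluate_surface(energy_fn, grid: GridSurface) -> GridSurface:
    """Fill the grid's energies; failed nodes become NaN (all failing raises)."""
    E = np.empty((len(grid.c1), len(grid.c2)))
    n_failed = 0
    for i in range(len(grid.c1)):
        for j in range(len(grid.c2)):
            try:
                E[i, j] = float(energy_fn(grid.nodes[i, j]))
            except Exception:
                E[i, j] = np.nan
                n_failed += 1
    if n_failed == E.size:
        raise ValueError("energy evaluation failed on every grid node")
    grid.energies = E
    grid.metadata["n_failed_nodes"] = n_failed
    return grid


def classify_stationary_point(
    surface: GridSurface, node: tuple[int, int] | None = None, grad_factor: float = 0.05
) -> str:
    """Classify a grid node as minimum / maximum / saddle / nonstationary.

    Central-difference gradient and Hessian on the grid.  The node counts as
    stationary when the gradient norm is below
    ``grad_factor * energy_range / spacing`` — a threshold scaled to the
    surface so the verdict does not depend on units; the classification then
    follows the signs of the 2x2 Hessian eigenvalues.
    """
    if surface.energies is None:
        raise ValueError("evaluate_surface first")
    i, j = node if node is not None else surface.anchor_node
    n1, n2 = surface.energies.shape
    if not (0 < i < n1 - 1 and 0 < j < n2 - 1):
        raise ValueError("node must be interior to the grid")
    E = surface.energies
    h1 = surface.c1[1] - surface.c1[0]
    h2 = surface.c2[1] - surface.c2[0]
    window = E[i - 1 : i + 2, j - 1 : j + 2]
    if not np.all(np.isfinite(window)):
        raise ValueError("NaN energies in the stencil around the node")
    g = np.array([(E[i + 1, j] - E[i - 1, j]) / (2 * h1), (E[i, j + 1] - E[i, j - 1]) / (2 * h2)])
    H = np.array(
        [
            [
                (E[i + 1, j] - 2 * E[i, j] + E[i - 1, j]) / h1**2,
                (E[i + 1, j + 1] - E[i + 1, j - 1] - E[i - 1, j + 1] + E[i - 1, j - 1])
                / (4 * h1 * h2),
            ],
            [0.0, (E[i, j + 1] - 2 * E[i, j] + E[i, j - 1]) / h2**2],
        ]
    )
    H[1, 0] = H[0, 1]
    finite = E[np.isfinite(E)]
    e_range = float(finite.max() - finite.min())
    thresh = grad_factor * e_range / min(abs(h1), abs(h2))
    if e_range == 0.0 or np.linalg.norm(g) < thresh:
        evals = np.linalg.eigvalsh(H)
        curv_floor = 1e-10 * max(e_range, 1.0) / min(h1, h2) ** 2
        if np.all(evals > curv_floor):
            return "minimum"
        if np.all(evals < -curv_floor):
            return "maximum"
        if evals[0] < -curv_floor and evals[-1] > curv_floor:
            return "saddle"
        return "nonstationary"  # degenerate flat direction
    return "nonstationary"


def free_energy_surface(
    samples: np.ndarray, beta: float, bins: int | tuple[int, int] = 30
) -> dict:
    """Histogram Boltzmann inversion of sampled CV pairs.

    ``F = -(1/beta) log(density)`` on a 2-D histogram, shifted so the minimum
    is 0; empty bins are NaN.  Returns the grid edges, bin centers and F,
    plus metadata flagging the estimator as a simple histogram inversion.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != 2:
        raise ValueError("samples must be (n, 2) CV pairs")
    if beta <= 0:
        raise ValueError("beta must be positive")
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    if np.allclose(samples.std(axis=0), 0.0):
        raise ValueError("degenerate single-point sample cloud")
    hist, e1, e2 = np.histogram2d(samples[:, 0], samples[:, 1], bins=bins, density=True)
    with np.errstate(divide="ignore"):
        F = -np.log(hist) / beta
    F[~np.isfinite(F)] = np.nan
    F = F - np.nanmin(F)
    return {
        "centers1": 0.5 * (e1[:-1] + e1[1:]),
        "centers2": 0.5 * (e2[:-1] + e2[1:]),
        "free_energy": F,
        "edges1": e1,
        "edges2": e2,
        "metadata": {"estimator": "histogram Boltzmann inversion (stand-in estimator)",
                     "beta": float(beta), "n_samples": int(len(samples))},
    }
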