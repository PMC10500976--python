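"""Diffusion-map construction and spectral analysis of MD snapshot sets.

The pipeline is: pairwise distances (wrapped-angle metric) -> Gaussian kernel
(constant, alpha-normalized, energy-based, locally scaled, or weighted) ->
row-stochastic transition matrix P -> approximate backward Kolmogorov
generator L = (P - I)/eps_eff -> eigenpairs -> diffusion coordinates.

Kernel conventions
------------------
The constant kernel is ``A_ij = exp(-d_ij^2 / eps)`` (``eps`` carries units of
squared distance); the locally scaled kernel is
``A_ij = exp(-d_ij^2 / (eps_i eps_j))`` with ``eps_i`` the distance from
sample ``i`` to its k-th nearest neighbor, ``k = max(1, ceil(r (n-1)))``.
Weighted kernels multiply by per-sample factors ``w_i w_j``; the
alpha-normalization divides by ``(p_i p_j)^alpha`` with ``p_i`` the kernel
row sums.

Generator scale
---------------
For a Gaussian kernel ``exp(-d^2/eps)`` on samples from the Boltzmann measure
``exp(-beta U)``, the alpha = 1/2 normalized transition matrix satisfies
``(P - I) f ~ (eps/4) (Delta f - beta grad U . grad f) = (eps beta / 4) L f``
with ``L = -grad U . grad + beta^{-1} Delta`` the backward Kolmogorov
operator.  The generator therefore divides by ``eps_eff = eps * beta / 4``
(for local scaling, ``eps`` is the geometric mean of the pairwise bandwidth
products, i.e. ``geomean(eps_i)^2``), so its nontrivial eigenvalues are on
the scale of the continuous operator's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .coordinates import FeatureSeries, pairwise_feature_distances

__all__ = [
    "KernelConfig",
    "DiffusionMapModel",
    "local_scales",
    "build_kernel",
    "alpha_normalize",
    "transition_matrix",
    "generator",
    "spectral_decompose",
    "diffusion_coordinates",
    "diffusion_distance",
    "build_diffusion_map",
]

KERNEL_KINDS = ("constant", "alpha_normalized", "energy_based", "locally_scaled", "weighted")
WEIGHT_MODES = ("ones", "inv_density", "energy", "tmd")

# Dense linear algebra only; the trajectories this targets are a few thousand
# frames.  Beyond the cap the quadratic memory cost is a mistake, not a job.
MAX_SAMPLES = 10_000


@dataclass(frozen=True)
class KernelConfig:
    """Settings selecting one member of the diffusion-map kernel family.

    kind:
        "constant"        A_ij = exp(-d^2/eps)
        "alpha_normalized" constant kernel followed by (p_i p_j)^-alpha
        "energy_based"     w_i w_j exp(-d^2/eps), w = exp(-beta U / 2)
        "locally_scaled"   exp(-d^2/(eps_i eps_j)), then alpha-normalized
        "weighted"         w_i w_j exp(-d^2/(eps_i eps_j)), w per weight_mode
    epsilon:
        Global bandwidth (squared-distance units) for constant-scale kinds;
        ``None`` selects the median-squared-distance heuristic
        ``eps = epsilon_factor * median(d_ij^2)``.
    r:
        Neighborhood fraction in (0, 1) defining the per-sample scales.
    alpha:
        Density-normalization exponent in [0, 1]; 1/2 recovers the backward
        Kolmogorov operator for Boltzmann-distributed samples.
    beta:
        Inverse temperature (consistent with the energy unit); required by
        energy-derived weights and used in the generator scale.
    weight_mode:
        "ones", "inv_density" (w=1/p), "energy" (w=exp(-beta U/2)) or "tmd"
        (target-measure weighting ``w_i = exp(-beta U_i/2) eps_i^{(d-2)/2}
        / p_i``, with ``p`` the unweighted-kernel row sums): the
        density-and-bandwidth-corrected weight under which the generator
        converges to the backward Kolmogorov operator for the Boltzmann
        measure regardless of how the snapshots were sampled.  The
        bandwidth factor (trivial for constant-scale kernels) cancels the
        spurious drift a sampling-dependent k-NN bandwidth otherwise
        induces; see docs/methods.md for the expansion.
    intrinsic_dim:
        Dimension ``d`` entering the tmd bandwidth exponent; ``None`` uses
        the ambient feature dimension (appropriate when the data fill it).
    """

    kind: str = "locally_scaled"
    epsilon: float | None = None
    epsilon_factor: float = 0.05
    r: float = 0.1
    alpha: float = 0.5
    beta: float = 1.0
    weight_mode: str = "energy"
    intrinsic_dim: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; choose from {KERNEL_KINDS}")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.kind in ("locally_scaled", "weighted") and not 0.0 < self.r < 1.0:
            raise ValueError("r must lie in (0, 1) for locally scaled kernels")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class DiffusionMapModel:
    """A constructed diffusion map with its spectral decomposition.

    ``eigenvalues`` are the eigenvalues of the transition matrix P, sorted
    descending from 1; ``generator_eigenvalues = (lam - 1)/eps_eff`` are the
    corresponding approximate Kolmogorov-operator eigenvalues (ascending in
    magnitude, leading one ~ 0).  ``dcs`` holds diffusion coordinates: column
    ``j`` is ``lam_{j+2} psi_{j+2}``, labelled DC2, DC3, ... following the
    convention that the constant mode is mode 1.
    """

    config: KernelConfig
    kernel_matrix: np.ndarray
    transition_matrix: np.ndarray
    local_scales: np.ndarray | None
    epsilon_effective: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dcs: np.ndarray
    dc_labels: list[str]
    stationary_weights: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def generator_eigenvalues(self) -> np.ndarray:
        return (self.eigenvalues - 1.0) / self.epsilon_effective

    def generator_matrix(self) -> np.ndarray:
        return generator(self.transition_matrix, self.epsilon_effective)

    def save(self, path) -> None:
        """Archive the spectral content (eigenpairs, DCs, scales) as NPZ.

        The dense kernel and transition matrices are recomputable from the
        data and config; the archive keeps only what downstream analysis
        reads back.
        """
        from dataclasses import asdict

        np.savez(
            path,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            dcs=self.dcs,
            dc_labels=np.array(self.dc_labels),
            local_scales=(
                np.array([]) if self.local_scales is None else self.local_scales
            ),
            epsilon_effective=self.epsilon_effective,
            config_json=np.array(json.dumps(asdict(self.config))),
        )

    @staticmethod
    def load_spectral(path) -> dict:
        """Read back a saved archive as a plain dict of arrays + config."""
        with np.load(path, allow_pickle=False) as npz:
            out = {k: npz[k] for k in npz.files}
        out["dc_labels"] = [str(s) for s in out["dc_labels"]]
        out["config"] = KernelConfig(**json.loads(str(out.pop("config_json"))))
        if out["local_scales"].size == 0:
            out["local_scales"] = None
        return out


def local_scales(distances: np.ndarray, r: float) -> np.ndarray:
    """Per-sample bandwidths from the k-nearest-neighbor criterion.

    ``eps_i`` is the distance from sample i to its k-th nearest neighbor with
    ``k = max(1, ceil(r (n-1)))``.  Duplicated points can make ``eps_i = 0``;
    those entries are floored at a machine-scaled epsilon with a warning so
    the kernel stays finite.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for local scales")
    if not 0.0 < r < 1.0:
        raise ValueError("r must lie in (0, 1)")
    k = max(1, int(np.ceil(r * (n - 1))))
    # k-th nearest neighbor excluding self: partition row without diagonal
    eps = np.empty(n)
    for i in range(n):
        row = np.delete(D[i], i)
        eps[i] = np.partition(row, k - 1)[k - 1]
    if np.any(eps <= 0.0):
        floor = max(np.max(D), 1.0) * 1e-12
        warnings.warn(
            "duplicate samples produced zero local scales; flooring at "
            f"{floor:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        eps = np.maximum(eps, floor)
    return eps


def _resolve_epsilon(distances: np.ndarray, config: KernelConfig) -> float:
    if config.epsilon is not None:
        return float(config.epsilon)
    iu = np.triu_indices_from(distances, k=1)
    med = float(np.median(distances[iu] ** 2))
    if med <= 0:
        raise ValueError("all pairwise distances are zero; cannot pick a bandwidth")
    return config.epsilon_factor * med


def _weights(
    config: KernelConfig,
    row_sums: np.ndarray,
    energies: np.ndarray | None,
    eps_local: np.ndarray | None = None,
    dim: int | None = None,
) -> np.ndarray:
    if config.weight_mode == "ones":
        return np.ones_like(row_sums)
    if config.weight_mode == "inv_density":
        return 1.0 / row_sums
    if energies is None:
        raise ValueError(f"weight_mode={config.weight_mode!r} requires per-frame energies")
    e = np.asarray(energies, dtype=float)
    # subtract the minimum before exponentiating: w enters the transition
    # matrix only up to a global factor, and this avoids overflow
    w = np.exp(-config.beta * (e - e.min()) / 2.0)
    if config.weight_mode == "tmd":
        w = w / row_sums
        if eps_local is not None:
            d = config.intrinsic_dim if config.intrinsic_dim is not None else dim
            if d is None:
                raise ValueError("tmd weights with local scales need the feature dimension")
            w = w * eps_local ** ((d - 2) / 2.0)
    return w


def build_kernel(
    features: FeatureSeries | np.ndarray,
    config: KernelConfig,
    energies: np.ndarray | None = None,
    distances: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Construct the (pre-normalization) kernel matrix for a snapshot set.

    Returns ``(A, eps_local, eps_scale)`` where ``eps_local`` is the vector of
    per-sample bandwidths (``None`` for constant-scale kinds) and
    ``eps_scale`` is the single squared-distance scale entering the generator
    quotient (the constant eps, or ``geomean(eps_i)^2``).
    """
    if isinstance(features, FeatureSeries):
        dim = features.dimension
    else:
        dim = np.atleast_2d(np.asarray(features)).shape[1] if features is not None else None
    if distances is None:
        distances = pairwise_feature_distances(features)
    D = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite pairwise distances")
    n = D.shape[0]
    if n > MAX_SAMPLES:
        raise ValueError(f"{n} samples exceeds the dense-matrix cap of {MAX_SAMPLES}")

    if config.kind in ("constant", "alpha_normalized", "energy_based"):
        eps = _resolve_epsilon(D, config)
        A = np.exp(-(D**2) / eps)
        eps_local = None
        eps_scale = eps
    else:
        eps_local = local_scales(D, config.r)
        A = np.exp(-(D**2) / np.outer(eps_local, eps_local))
        eps_scale = float(np.exp(2.0 * np.mean(np.log(eps_local))))

    if config.kind == "energy_based":
        if energies is None:
            raise ValueError("energy_based kernel requires per-frame energies")
        w = _weights(replace(config, weight_mode="energy"), A.sum(axis=1), energies)
        A = A * np.outer(w, w)
    elif config.kind == "weighted":
        w = _weights(config, A.sum(axis=1), energies, eps_local=eps_local, dim=dim)
        A = A * np.outer(w, w)
    return A, eps_local, eps_scale


def alpha_normalize(K: np.ndarray, alpha: float) -> np.ndarray:
    """Divide ``K_ij`` by ``(p_i p_j)^alpha`` with ``p`` the row sums.

    alpha = 0 leaves the kernel unchanged; alpha = 1 removes the sampling
    density entirely; alpha = 1/2 is the backward-Kolmogorov choice for
    Boltzmann-distributed samples.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 0.0:
        return np.array(K, dtype=float, copy=True)
    p = K.sum(axis=1)
    if np.any(p <= 0):
        raise ValueError("zero kernel row sum; cannot alpha-normalize")
    s = p ** (-alpha)
    return K * np.outer(s, s)


def transition_matrix(A_tilde: np.ndarray) -> np.ndarray:
    """Row-normalize a symmetric nonnegative kernel into a stochastic matrix."""
    d = A_tilde.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero row sum; cannot form transition matrix")
    return A_tilde / d[:, None]


def generator(P: np.ndarray, epsilon_effective: float) -> np.ndarray:
    """Approximate Kolmogorov generator ``L = (P - I)/eps_eff``.

    Rows sum to zero and the eigenvalue of smallest magnitude is 0 with a
    constant eigenvector, mirroring the continuous operator's null mode.
    """
    if epsilon_effective <= 0:
        raise ValueError("epsilon_effective must be positive")
    return (P - np.eye(P.shape[0])) / epsilon_effective


def spectral_decompose(A_tilde: np.ndarray, n_modes: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenpairs of ``P = D^-1 A~`` via its symmetric conjugate.

    ``S = D^-1/2 A~ D^-1/2`` shares P's (real) spectrum; its orthonormal
    eigenvectors map to right eigenvectors of P through ``D^-1/2``.  The
    dense LAPACK subset solver is used throughout: iterative solvers stall
    on the tightly clustered spectra that small-bandwidth kernels produce.
    Returns eigenvalues sorted descending and unit-norm eigenvectors with
    signs fixed so each vector's largest-magnitude entry is positive.
    """
    n = A_tilde.shape[0]
    if n_modes > n:
        raise ValueError(f"n_modes={n_modes} exceeds sample count {n}")
    d = A_tilde.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("zero row sum in kernel")
    s = 1.0 / np.sqrt(d)
    S = A_tilde * np.outer(s, s)
    S = 0.5 * (S + S.T)  # enforce exact symmetry
    vals, vecs = scipy.linalg.eigh(S, subset_by_index=[n - n_modes, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    psi = vecs * s[:, None]
    psi /= np.linalg.norm(psi, axis=0)
    flip = np.sign(psi[np.argmax(np.abs(psi), axis=0), np.arange(psi.shape[1])])
    psi *= np.where(flip == 0, 1.0, flip)
    return vals, psi


def diffusion_coordinates(
    eigenvalues: np.ndarray, eigenvectors: np.ndarray, t: float = 1.0, k: int | None = None
) -> tuple[np.ndarray, list[str]]:
    """Per-snapshot diffusion coordinates from nontrivial eigenpairs.

    Component ``j`` is ``lam_{j+2}^t psi_{j+2}``; the constant leading mode is
    excluded.  Labels start at "DC2" so the second eigenvector of P carries
    the first nontrivial coordinate, matching the usual numbering.
    """
    avail = len(eigenvalues) - 1
    if k is None:
        k = avail
    if k < 1 or k > avail:
        raise ValueError(f"k must lie in [1, {avail}]")
    lams = eigenvalues[1 : k + 1]
    dcs = eigenvectors[:, 1 : k + 1] * np.sign(lams) * np.abs(lams) ** t
    labels = [f"DC{j + 2}" for j in range(k)]
    return dcs, labels


def diffusion_distance(dc_x: np.ndarray, dc_y: np.ndarray) -> float:
    """L2 distance between two snapshots in diffusion-coordinate space."""
    dc_x = np.asarray(dc_x, dtype=float)
    dc_y = np.asarray(dc_y, dtype=float)
    if dc_x.shape != dc_y.shape:
        raise ValueError("diffusion-coordinate length mismatch")
    return float(np.linalg.norm(dc_x - dc_y))


def build_diffusion_map(
    features: FeatureSeries | np.ndarray,
    config: KernelConfig | None = None,
    energies: np.ndarray | None = None,
    n_modes: int = 8,
    t: float = 1.0,
    distances: np.ndarray | None = None,
    compute_spectrum: bool = True,
) -> DiffusionMapModel:
    """Full pipeline: kernel -> normalization -> P -> eigenpairs -> DCs.

    ``compute_spectrum=False`` skips the eigendecomposition (the committor
    boundary-value solve needs only the transition matrix); the model then
    carries empty eigenpairs and no diffusion coordinates.
    """
    if config is None:
        config = KernelConfig()
    A, eps_local, eps_scale = build_kernel(features, config, energies=energies, distances=distances)
    if config.kind in ("alpha_normalized", "locally_scaled"):
        A_tilde = alpha_normalize(A, config.alpha)
    else:
        A_tilde = A
    P = transition_matrix(A_tilde)
    n_modes = min(n_modes, P.shape[0])
    if compute_spectrum:
        vals, vecs = spectral_decompose(A_tilde, n_modes)
        dcs, labels = diffusion_coordinates(vals, vecs, t=t)
    else:
        vals = np.array([1.0])  # leading eigenvalue of any stochastic matrix
        vecs = np.full((P.shape[0], 1), 1.0 / np.sqrt(P.shape[0]))
        dcs, labels = np.empty((P.shape[0], 0)), []
    eps_eff = eps_scale * config.beta / 4.0
    model = DiffusionMapModel(
        config=config,
        kernel_matrix=A,
        transition_matrix=P,
        local_scales=eps_local,
        epsilon_effective=eps_eff,
        eigenvalues=vals,
        eigenvectors=vecs,
        dcs=dcs,
        dc_labels=labels,
        stationary_weights=A_tilde.sum(axis=1),
    )
    _validate_model(model)
    return model


def _validate_model(model: DiffusionMapModel) -> None:
    P = model.transition_matrix
    if np.any(P < -1e-14):
        raise AssertionError("negative transition-matrix entries")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
        raise AssertionError("transition-matrix rows do not sum to 1")
    if abs(model.eigenvalues[0] - 1.0) > 1e-8:
        raise AssertionError("leading transition eigenvalue differs from 1")
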