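"""End-to-end orchestration of the two analysis workflows.

``run_local_analysis``: trajectory -> internal coordinates -> QSD-monitored
local diffusion map -> truncation -> DC2/DC3 -> CV correlation table and
ranking.

``run_committor_analysis``: trajectory (ensemble) -> global diffusion map ->
basin definition -> committor boundary-value solve -> isocommittor band and
free-energy surface.

Both write their tables plus a manifest echoing every resolved parameter, so
any artifact can be regenerated from its manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .committor import define_basins, isocommittor_band, solve_committor
from .coordinates import FeatureSeries, Trajectory, compute_internal_coordinates, kabsch_align
from .cv import correlation_table, pc_coefficients, pca_fit, rank_cvs
from .dmap import KernelConfig, build_diffusion_map
from .pes import free_energy_surface
from .qsd import detect_stabilization, monitor_qsd

__all__ = ["RunConfig", "run_local_analysis", "run_committor_analysis"]


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run; echoed verbatim into the manifest."""

    output_dir: str
    kernel: KernelConfig = field(default_factory=KernelConfig)
    feature_choice: str = "internal"  # "internal" | "aligned_cartesian" | "raw"
    qsd_m: int = 100
    qsd_n_track: int = 5
    qsd_rel_tol: float = 0.3
    qsd_window: int = 3
    qsd_min_frames: int = 1500
    qsd_max_check_size: int = 2000
    basin_cutoff: float = 0.2
    n_pcs: int = 3
    dc_count: int = 2
    iso_level: float = 0.5
    iso_tol: float = 0.05
    fes_bins: int = 30
    seed: int = 0
    min_frames_after_truncation: int = 100

    def __post_init__(self) -> None:
        if self.feature_choice not in ("internal", "aligned_cartesian", "raw"):
            raise ValueError(f"unknown feature_choice {self.feature_choice!r}")
        if self.min_frames_after_truncation < 2:
            raise ValueError("min_frames_after_truncation must be >= 2")


def _extract_features(traj_or_features, config: RunConfig, topology=None) -> FeatureSeries:
    if isinstance(traj_or_features, FeatureSeries):
        return traj_or_features
    if isinstance(traj_or_features, np.ndarray):
        return FeatureSeries.from_array(traj_or_features)
    traj: Trajectory = traj_or_features
    if config.feature_choice == "internal":
        if topology is None:
            raise ValueError("feature_choice='internal' requires a topology")
        return compute_internal_coordinates(traj, topology)
    if config.feature_choice == "aligned_cartesian":
        aligned, _ = kabsch_align(traj, traj.frames[0])
        flat = aligned.frames.reshape(traj.n_frames, -1)
        names = [f"{ax}{i}" for i in range(traj.n_atoms) for ax in "xyz"]
        return FeatureSeries.from_array(flat, names=names)
    return FeatureSeries.from_array(traj.frames.reshape(traj.n_frames, -1))


def _manifest(config: RunConfig, extra: dict) -> dict:
    data = asdict(config)
    data["kernel"] = asdict(config.kernel)
    data.update(extra)
    return data


def run_local_analysis(
    traj_or_features,
    config: RunConfig,
    topology=None,
    energies: np.ndarray | None = None,
) -> dict:
    """QSD-checked local diffusion map followed by CV assessment.

    Returns the QSD trace, the truncation index, the diffusion-map model on
    the truncated prefix, and the CV correlation table / ranking; writes
    ``qsd_trace.csv``, ``correlation_table.csv``, ``cv_ranking.csv`` and
    ``manifest.yaml`` under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = _extract_features(traj_or_features, config, topology)
    if energies is None and isinstance(traj_or_features, Trajectory):
        energies = traj_or_features.energies
    if energies is None and config.kernel.kind in ("energy_based", "weighted") and \
            config.kernel.weight_mode in ("energy", "tmd"):
        raise ValueError("energy-weighted kernel requested but no energies available")

    trace = monitor_qsd(
        features,
        m=config.qsd_m,
        n_track=config.qsd_n_track,
        kernel=config.kernel,
        energies=energies,
        max_check_size=config.qsd_max_check_size,
    )
    truncation = detect_stabilization(
        trace,
        rel_tol=config.qsd_rel_tol,
        window=config.qsd_window,
        min_frames=config.qsd_min_frames,
    )
    if truncation < config.min_frames_after_truncation:
        raise RuntimeError(
            f"QSD truncation keeps only {truncation} frames "
            f"(< {config.min_frames_after_truncation}); the trajectory never stabilizes"
        )
    kept = FeatureSeries(
        values=features.values[:truncation],
        is_angular=features.is_angular,
        names=features.names,
    )
    kept_energies = None if energies is None else energies[:truncation]
    model = build_diffusion_map(kept, config.kernel, energies=kept_energies,
                               n_modes=config.dc_count + 2)

    dcs = {model.dc_labels[j]: model.dcs[:, j] for j in range(config.dc_count)}
    cvs: dict[str, np.ndarray] = {
        name: kept.values[:, k] for k, name in enumerate(kept.names)
    }
    pca = pca_fit(kept)
    for j in range(min(config.n_pcs, pca.n_components)):
        cvs[f"PC{j + 1}"] = pc_coefficients(kept, pca, j)
    table = correlation_table(cvs, dcs)
    ranking = rank_cvs(table, dc=model.dc_labels[0])

    trace_df = pd.DataFrame(
        trace.eigenvalue_traces,
        columns=[f"lambda{k + 1}" for k in range(trace.eigenvalue_traces.shape[1])],
    )
    trace_df.insert(0, "frames_used", trace.check_indices)
    trace_df["stabilized"] = trace.stabilized
    trace_df.to_csv(out / "qsd_trace.csv", index=False)
    table.to_csv(out / "correlation_table.csv")
    ranking.to_csv(out / "cv_ranking.csv")
    dio.write_yaml(
        out / "manifest.yaml",
        _manifest(config, {
            "stage": "local_analysis",
            "n_frames_input": int(features.n_frames),
            "truncation_index": int(truncation),
            "n_checks": int(trace.n_checks),
            "pca_singular_values": [float(s) for s in pca.singular_values],
        }),
    )
    return {
        "trace": trace,
        "truncation_index": truncation,
        "model": model,
        "pca": pca,
        "correlation_table": table,
        "ranking": ranking,
    }


def run_committor_analysis(
    traj_or_features,
    config: RunConfig,
    reactant_ref: np.ndarray,
    product_ref: np.ndarray,
    topology=None,
    energies: np.ndarray | None = None,
    cv_pair: tuple[int, int] = (0, 1),
    beta: float | None = None,
) -> dict:
    """Global diffusion map, committor solve, and transition-region reports.

    ``reactant_ref``/``product_ref`` are reference configurations in the same
    feature space the map is built on.  Writes ``committor.csv`` (frame, q,
    basin label), a free-energy grid over ``cv_pair`` when the feature space
    has >= 2 dimensions, and a manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    features = _extract_features(traj_or_features, config, topology)
    if energies is None and isinstance(traj_or_features, Trajectory):
        energies = traj_or_features.energies
    reactant_ref = np.asarray(reactant_ref, dtype=float).reshape(-1)
    product_ref = np.asarray(product_ref, dtype=float).reshape(-1)
    if reactant_ref.size != features.dimension or product_ref.size != features.dimension:
        raise ValueError("basin references must live in the feature space")

    model = build_diffusion_map(
        features, config.kernel, energies=energies, compute_spectrum=False
    )
    A, B = define_basins(features, reactant_ref, product_ref, config.basin_cutoff)
    solution = solve_committor(model, A, B)
    band = isocommittor_band(solution, level=config.iso_level, tol=config.iso_tol)

    labels = np.array(["interior"] * features.n_frames, dtype=object)
    labels[A.indices] = "A"
    labels[B.indices] = "B"
    pd.DataFrame(
        {"frame": np.arange(features.n_frames), "q": solution.q, "basin": labels}
    ).to_csv(out / "committor.csv", index=False)

    fes = None
    if features.dimension >= 2:
        i, j = cv_pair
        fes = free_energy_surface(
            features.values[:, [i, j]],
            beta=beta if beta is not None else config.kernel.beta,
            bins=config.fes_bins,
        )
        grid = pd.DataFrame(fes["free_energy"],
                            index=fes["centers1"], columns=fes["centers2"])
        grid.to_csv(out / "free_energy_surface.csv")

    dio.write_yaml(
        out / "manifest.yaml",
        _manifest(config, {
            "stage": "committor_analysis",
            "n_frames": int(features.n_frames),
            "n_A": int(A.indices.size),
            "n_B": int(B.indices.size),
            "residual": float(solution.residual),
            "isocommittor_band_size": int(band.size),
            "cv_pair": [int(cv_pair[0]), int(cv_pair[1])],
        }),
    )
    return {"model": model, "solution": solution, "band": band, "fes": fes,
            "basin_a": A, "basin_b": B}
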