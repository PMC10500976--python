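"""Shared fixtures: synthetic runs and models reused across test modules.

Heavy simulations and diffusion-map builds are session-scoped so the suite
pays for each study condition once.
"""

from __future__ import annotations

import numpy as np
import pytest

from dmapcv import committor as cm
from dmapcv import dmap, qsd, synthetic

BETA_DW = 3.0


@pytest.fixture(scope="session")
def double_well():
    return synthetic.double_well_1d(h=5.0, beta=BETA_DW)


@pytest.fixture(scope="session")
def two_well():
    return synthetic.two_well_2d()


@pytest.fixture(scope="session")
def ou_system():
    return synthetic.ou_1d(k=2.0, beta=1.0)


@pytest.fixture(scope="session")
def triatomic():
    return synthetic.toy_triatomic()


@pytest.fixture(scope="session")
def confined_run(double_well):
    """4000-frame Langevin run confined to the product basin (never hops)."""
    return synthetic.simulate_langevin(
        double_well, np.array([1.0]), dt=1e-3, n_steps=4000, seed=0, include_initial=False
    )


@pytest.fixture(scope="session")
def confined_trace(confined_run):
    return qsd.monitor_qsd(confined_run.positions, m=100, energies=confined_run.energies)


@pytest.fixture(scope="session")
def hop_run():
    """Seed-selected low-barrier run with a clean hop at a labeled step."""
    run, hop_step, seed = synthetic.find_hopping_run(seed_start=0)
    return run, hop_step, seed


@pytest.fixture(scope="session")
def barrier_ensemble(double_well):
    """4021-frame shooting ensemble from the barrier (60 runs x 67 steps)."""
    return synthetic.barrier_shooting_ensemble(
        double_well, n_runs=60, n_steps=67, dt=1e-3, seed=0
    )


@pytest.fixture(scope="session")
def committor_kernel():
    return dmap.KernelConfig(kind="weighted", r=0.002, beta=BETA_DW, weight_mode="tmd")


@pytest.fixture(scope="session")
def committor_solution(barrier_ensemble, committor_kernel):
    """Global diffusion map + solved committor on the barrier ensemble."""
    model = dmap.build_diffusion_map(
        barrier_ensemble.positions,
        committor_kernel,
        energies=barrier_ensemble.energies,
        compute_spectrum=False,
    )
    A, B = cm.define_basins(
        barrier_ensemble.positions, np.array([-1.0]), np.array([1.0]), cutoff=0.4
    )
    return model, cm.solve_committor(model, A, B)


@pytest.fixture(scope="session")
def analytic_q(double_well, barrier_ensemble):
    """Closed-form committor evaluated on the ensemble's frames."""
    qa = synthetic.analytic_committor_1d(double_well, -1.0, 1.0)
    return np.atleast_1d(qa(barrier_ensemble.positions[:, 0]))


@pytest.fixture(scope="session")
def ou_samples(ou_system):
    """2000 near-independent equilibrium samples of the OU process."""
    res = synthetic.simulate_langevin(
        ou_system,
        np.array([0.0]),
        dt=1e-3,
        n_steps=100_000,
        seed=3,
        stride=50,
        include_initial=False,
    )
    return res.positions


@pytest.fixture(scope="session")
def ou_dmap(ou_samples):
    cfg = dmap.KernelConfig(kind="alpha_normalized", alpha=0.5, beta=1.0, epsilon_factor=0.05)
    return dmap.build_diffusion_map(ou_samples, cfg, n_modes=4)


@pytest.fixture(scope="session")
def basin_run_2d(two_well):
    """2000-frame run confined to the x = +1 basin of the 2-D system."""
    return synthetic.simulate_langevin(
        two_well, np.array([1.0, 0.0]), dt=1e-3, n_steps=2000, seed=0, include_initial=False
    )


@pytest.fixture(scope="session")
def local_dmap_2d(basin_run_2d):
    cfg = dmap.KernelConfig(kind="weighted", r=0.1, beta=BETA_DW, weight_mode="energy")
    return dmap.build_diffusion_map(
        basin_run_2d.positions, cfg, energies=basin_run_2d.energies, n_modes=4
    )
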