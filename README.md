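# dmapcv — diffusion-map analysis of reaction dynamics

`dmapcv` is an analysis toolkit for molecular-dynamics snapshots of reactive
systems. It answers two questions practitioners face when a reaction's
mechanism is not obvious from chemical intuition:

1. **Which candidate collective variables (CVs) actually track the slow,
   reactive motion?** Internal coordinates (bond lengths, angles, dihedrals)
   and principal components are ranked by their correlation with the leading
   diffusion coordinates of a *local* diffusion map, built from snapshots
   confined to a metastable basin — valid once those snapshots have relaxed
   to the basin's quasi-stationary distribution (QSD), which the package
   verifies by monitoring the map's leading eigenvalues.
2. **Where is the transition region?** A *global* diffusion map over
   trajectories spanning reactant and product basins yields a discrete
   committor function — the probability `q(x)` of reaching the product basin
   B before the reactant basin A — by solving a boundary-value linear
   system; the isocommittor surface `q = 0.5` locates the dynamical
   transition state.

The library targets overdamped Langevin dynamics
`dx = -∇U(x) dt + √(2/β) dW` with backward Kolmogorov generator
`L = -∇U·∇ + β⁻¹Δ`. From snapshots `{x_i}` it builds a Gaussian kernel
`A_ij = exp(-d²(x_i,x_j)/(ε_i ε_j))` (constant-ε, density-normalized,
energy-weighted and k-nearest-neighbor locally scaled variants), normalizes
it to a row-stochastic matrix `P`, and uses `(P - I)/ε_eff → L` to
approximate the generator's spectrum, eigenvectors (diffusion coordinates
DC2, DC3, …) and committors. Distances between feature vectors wrap angular
dimensions so that two angles are never more than π apart.

Everything is exercised on synthetic systems with analytic ground truth
(double wells, an Ornstein–Uhlenbeck process with known spectrum
`λ_j = -jk`, a toy triatomic with an analytic saddle), including closed-form
and shooting-simulation committors and a finite-difference discretization of
`L` — so every stage of the pipeline is validated against an independent
oracle.

## Layout

- `src/dmapcv/` — the library: `coordinates` (internal coordinates, angle
  wrapping, Kabsch alignment, coordination numbers), `dmap` (kernels,
  transition matrices, spectra, diffusion coordinates), `qsd`
  (quasi-stationarity monitoring), `cv` (PCA and correlation ranking),
  `committor` (basins and the boundary-value solve), `pes` (CV-plane energy
  surfaces and saddle classification), `synthetic` (Langevin samplers and
  oracles), `io` (extended-XYZ, topology YAML, feature CSV), `pipeline`
  (end-to-end orchestration).
- `analysis/01…06_*.py` — numbered drivers running the study end to end;
  each writes its tables under `results/`.
- `docs/methods.md` — the model, conventions, parameter choices and
  limitations.

## Worked example

Solve a committor on a barrier-initiated ensemble of the symmetric double
well `U(x) = 5(x²-1)²` at β = 3 (60 short Langevin runs launched at the
barrier top, 4021 frames total):

```python
import numpy as np
from dmapcv import committor as cm, dmap, synthetic

system = synthetic.double_well_1d(h=5.0, beta=3.0)
ens = synthetic.barrier_shooting_ensemble(system, n_runs=60, n_steps=67, seed=0)

cfg = dmap.KernelConfig(kind="weighted", r=0.002, beta=3.0, weight_mode="tmd")
model = dmap.build_diffusion_map(ens.positions, cfg, energies=ens.energies,
                                 compute_spectrum=False)
A, B = cm.define_basins(ens.positions, np.array([-1.0]), np.array([1.0]), cutoff=0.4)
sol = cm.solve_committor(model, A, B)

qa = synthetic.analytic_committor_1d(system, -1.0, 1.0)
err = cm.committor_validation(sol, np.atleast_1d(qa(ens.positions[:, 0])))
print(f"q at barrier frame: {sol.q[0]:.3f}")
print(f"interior RMSE vs analytic committor: {err['rmse']:.4f}")
```

prints

```
q at barrier frame: 0.506
interior RMSE vs analytic committor: 0.0036
```

`q ≈ 0.5` at the barrier is the committor signature of a transition state;
the RMSE compares all ~3900 interior frames against the closed-form
quadrature solution `q(x) = ∫_a^x e^{βU} ds / ∫_a^b e^{βU} ds`. Running the
drivers in order (`python analysis/03_qsd_monitoring.py`, …) prints the
corresponding results for QSD monitoring (40 checks on a 4000-frame
trajectory, truncation at a labeled basin hop), CV ranking (the engineered
slow coordinate tops the table at |ρ| ≈ 0.97 with DC2), spectral recovery
(data-driven eigenvalue −2.21 vs closed form −2), and saddle classification
of the toy triatomic's transition state.

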