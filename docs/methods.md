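# Methods

## Model and scope

All analysis assumes configurations sampled by overdamped Langevin dynamics

    dx_t = -∇U(x_t) dt + sqrt(2/β) dW_t,

whose backward Kolmogorov generator is `L = -∇U·∇ + β⁻¹Δ` with spectrum
`0 = λ₁ > λ₂ ≥ λ₃ ≥ …` and eigenfunctions `ψ_j`. The package estimates this
operator's spectral content from snapshots alone and uses it three ways:
eigenvalue traces as a stationarity (QSD) diagnostic, eigenvectors as
diffusion coordinates against which candidate CVs are ranked, and the
discrete generator as the linear operator in the committor boundary-value
problem. Inertial dynamics, thermostats other than the overdamped limit,
and periodic boundary conditions are out of scope.

## Feature spaces and conventions

Snapshots enter either as internal coordinates (bonds in Å, angles and
dihedrals in radians) or as rigid-body-aligned Cartesians. Conventions fixed
repo-wide:

- Angles are stored in `(-π, π]`; dihedrals follow the IUPAC sign
  convention. Exact trans arrangements map to `+π`.
- Distances between feature vectors wrap angular components: the
  contribution of an angle pair is `min(|Δθ| mod 2π, 2π - |Δθ| mod 2π)`,
  never exceeding π. Without this, two configurations straddling the branch
  cut acquire a spurious `2π - 2θ` separation that distorts the kernel.
- PCA maps each angular column to `(-π, π]` about its circular mean before
  the SVD, keeping tight angular distributions contiguous; columns are not
  z-scored by default (mixed-unit coordinates are analyzed in native units,
  an opt-in flag standardizes).
- Alignment uses the optimal (Kabsch) rotation per frame; with fewer than
  three non-collinear atoms the rotation is ill-posed and the code warns and
  applies the translation only.
- Coordination numbers use the Fermi–Dirac switch
  `CN_i = Σ_j 1/(1 + exp(κ(r_j - r_{0,j})))`. The switch width is not a
  settled constant in the field, so κ is exposed (default 10 Å⁻¹, a switch
  that turns over within ±0.2 Å of the equilibrium distance).

## Diffusion-map family

From pairwise distances `d_ij` the kernel is one of

| kind             | matrix                                               |
|------------------|------------------------------------------------------|
| constant         | `exp(-d²/ε)`                                         |
| alpha_normalized | constant kernel, then `Ã = A/(p_i p_j)^α`            |
| energy_based     | `w_i w_j exp(-d²/ε)` with `w = e^{-βU/2}`            |
| locally_scaled   | `exp(-d²/(ε_i ε_j))`, then α-normalized              |
| weighted         | `w_i w_j exp(-d²/(ε_i ε_j))`, `w` per `weight_mode`  |

with `p_i` the kernel row sums and `ε_i` the distance from sample `i` to its
k-th nearest neighbor, `k = max(1, ⌈r(n-1)⌉)`. The transition matrix is the
row normalization of the (weighted, normalized) kernel; eigen-solves run on
the symmetric conjugate `D^{-1/2} Ã D^{-1/2}` with a dense LAPACK subset
solver (iterative solvers stall on the tightly clustered spectra that
small-bandwidth kernels produce), and eigenvector signs are fixed so each
vector's largest-magnitude entry is positive. Diffusion coordinates are
`DC_{j+1} = λ_j^t ψ_j` for the nontrivial modes, labelled DC2, DC3, … with
the constant mode as mode 1. Dense matrices only; sample counts are capped
at 10,000.

**Generator scale.** A second-order expansion of the Gaussian kernel
integral gives, for α = 1/2 on Boltzmann-distributed samples,

    (P - I) f ≈ (ε/4) (Δf - β ∇U·∇f) = (εβ/4) L f,

so the generator quotient divides by `ε_eff = εβ/4`; for locally scaled
kernels ε is taken as the geometric mean of the pairwise bandwidth products,
`(geomean ε_i)²`. With this scale the data-driven eigenvalues land directly
on the continuous operator's scale (the OU benchmark below).

**Target-measure weights.** The `tmd` weight mode implements

    w_i = e^{-βU_i/2} · ε_i^{(d-2)/2} / p_i,

which makes the generator converge to `L` for the Boltzmann measure
*regardless of the sampling density* — essential for barrier-initiated
shooting ensembles, which oversample the transition region and split
unevenly between basins. The `ε_i^{(d-2)/2}` factor is specific to the
variable-bandwidth kernel: expanding `exp(-|u|²/(ε(x)ε(y)))` to the same
order adds a drift `((d+2)/2)∇log ε` absent from the constant-bandwidth
analysis, and with the kernel-density relation `p ∝ n ε^d q_s` the exponent
`(d-2)/2` is what cancels both the sampling-density and bandwidth-gradient
drifts. Without it, a k-NN bandwidth (ε ∝ density⁻¹) leaves a residual
drift toward the undersampled basin that biases barrier committor values by
~0.1 under a 20-run shooting split; with it the bias drops below 0.02.
`d` defaults to the ambient feature dimension; for data on a
lower-dimensional manifold it should be set to the intrinsic dimension
(`intrinsic_dim`).

**Bandwidth defaults.** The constant-ε heuristic is
`ε = 0.05 · median(d²)`, validated on the OU closed form: across seeds the
leading nontrivial eigenvalue lands within 5–15% of `-k` at n = 2000 (2000
near-independent samples, Langevin thinned at 50-step stride). Local maps
default to `r = 0.1`; global (committor) maps to `r = 0.002`, i.e. ~8
neighbors at n = 4000. Below n ≈ 2000 at `r = 0.002` the kernel graph can
disconnect; the committor solver detects this and reports the component
sizes rather than returning a singular solve.

## QSD monitoring

Every `m` frames (default 100) a diffusion map is rebuilt from all frames
seen so far — the full distance matrix is computed once and sliced, so each
check is identical to a from-scratch rebuild — and its first `n_track = 5`
generator eigenvalues are recorded. Prefixes beyond `max_check_size = 2000`
frames are subsampled at a deterministic uniform stride to bound the
eigensolve cost. The default kernel for monitoring is the weighted kernel
with energy-derived weights and `r = 0.1` local scales.

Truncation rule: the trajectory is cut at the check before the first check
at which any tracked eigenvalue deviates from its trailing-`window` mean
(window = 3) by more than `rel_tol = 0.3` relative; near-zero eigenvalues
are measured against a floor of 5% of the largest tracked magnitude so the
trivial null mode cannot alarm. Detection begins only once the prefix holds
`min_frames = 1500` frames. Both numbers are calibrated on the synthetic
systems: growing-prefix spectral estimates drift 30–60% while n < ~1500 on
*stationary* data (longest for soft anharmonic basins) and fluctuate up to
~26% thereafter, whereas a basin exit moves the slow eigenvalue by 40–65%
within one or two checks. With these defaults, stationary runs raise no
false alarms and labeled basin hops are localized within ±2 checks. The
eigenvalue-stability criterion itself is a heuristic with no canonical
threshold; the implemented rule is one defensible formalization, and both
knobs are exposed. Eigenvalues are tracked on the generator scale;
transition-matrix-scale tracking amounts to a per-check rescaling by
`ε_eff` and is available by reading the traces with `ε_eff` multiplied
back.

## Committor

Basins are balls (in the wrapped-angle feature metric) around reactant and
product references; overlapping assignments go to the nearer reference.
With `q = 0` on A and `q = 1` on B, the interior solve is
`(I - P_cc) q_c = P_cB 1` by dense LU; since any generator `S(P - I)` with
positive diagonal `S` has the same null space, the solution is independent
of the generator scale. The solver checks kernel-graph connectivity first
and reports the infinity-norm residual. Interior values then satisfy the
discrete maximum principle up to round-off. The default committor kernel is
`weighted`/`tmd` (above); the α-normalized and energy-based kernels remain
available and must be selected explicitly, since the appropriate
normalization is system-dependent in practice.

## PES projection and free energies

A CV pair `(u₁, u₂)` is validated by evaluating `E(c₁,c₂) =
U(z_ts + c₁u₁ + c₂u₂)` on a uniform grid anchored at the transition state
(`u` = standard basis columns for IC CVs, principal components for PCA
CVs) and classifying the anchored node from central-difference gradients
and Hessians. "Stationary" means the gradient norm is below
`0.05 × energy-range/spacing` — scaled to the surface so the verdict is
unit-free; classification then follows the Hessian eigenvalue signs with a
round-off curvature floor. An index-1 saddle at the anchor indicates the
pair resolves the barrier. IC-direction grids for the toy triatomic are
rebuilt from perturbed internal coordinates via its Z-matrix embedding;
general IC→Cartesian back-transformation is not attempted.

The free-energy estimator is a plain 2-D histogram Boltzmann inversion
`F = -(1/β) log(density)`, minimum shifted to zero, empty bins NaN. It is a
stand-in renderer for sampled CV clouds (flagged as such in its output
metadata), not a statistically efficient estimator: it has histogram bias,
no reweighting, and needs well-filled bins.

## Synthetic study systems

The generator module defines the conditions every test and the acceptance
script run under:

- `double_well_1d`: `U = h(x²-1)²`, defaults h = 5, β = 3, so the barrier is
  15 k_BT — hops are astronomically rare and basin-confined runs are cleanly
  metastable. The *hopping* fixture for change detection instead uses h = 1,
  β = 1 (barrier 1 k_BT, Kramers hop time ~3·10³ steps at dt = 10⁻³), with
  seed selection (`find_hopping_run`) requiring confinement below 0.1 until
  100 steps before a first crossing of +0.5 inside steps [1800, 3200]; runs
  with large pre-hop excursions are genuine distribution changes, not clean
  change-point fixtures.
- `two_well_2d`: adds a transverse harmonic mode with κ = 200 against a
  basin curvature 8h = 40, a 5× timescale separation that makes x the slow
  CV by construction.
- `ou_1d`: `U = kx²/2` with closed-form spectrum `λ_j = -jk`; the primary
  quantitative benchmark.
- `toy_triatomic` (H, O1, O2 in internal coordinates r₁ = H–O1, r₂ = O1–O2,
  θ): quartic double well in the reactive bond (minima 1.6 ± 0.45 Å, barrier
  h = 5), harmonic spectator bond (k₂ = 60) and bend (k_θ = 30), mimicking
  an association reaction's 2-bond + 1-angle topology with an analytic
  index-1 saddle. Within one basin the soft bend is the slowest mode — which
  is exactly what a local diffusion map should (and does) report.

Integration is Euler–Maruyama, matching the overdamped equation directly
and keeping the sampler trivially auditable; energies are recorded per
frame, runs are reproducible by seed, blow-ups raise naming the step.
Shooting ensembles record the launch configuration once and then each run's
post-launch frames, so the kernel never sees duplicated points. Their
default shape is 60 runs × 67 steps: at fixed total frames, the barrier
committor's seed-to-seed spread scales with 1/√(run count) (each run is one
independent barrier passage), and the many-short-runs design cuts it from
~0.026 to ~0.008 while the runs stay long enough to populate basin
neighborhoods of radius 0.4 (where the true committor already equals its
clamped value to < 10⁻⁴). Still shorter runs (50 steps) fail to reach the
basins at all.

Oracles are independent of the diffusion-map code path: the closed-form 1-D
committor by adaptive quadrature (log-shifted against overflow), an
empirical shooting committor with Agresti–Coull-shrunk binomial error bars
(undecided shots counted separately, never folded into either outcome), and
a central-difference discretization of `L` with reflecting boundaries whose
OU eigenvalue is exact to 0.04% at 400 grid points and which doubles as a
committor oracle (max deviation from the quadrature solution < 10⁻³).

What the synthetic conditions do **not** emulate: quantum-mechanical
potentials and forces, multi-scale molecular force fields, temperature
ladders, non-equilibrium initialization beyond barrier shooting, and
high-dimensional feature spaces with unknown intrinsic dimension. Passing
tests therefore demonstrate the estimators' correctness and calibration on
systems satisfying the model assumptions, not robustness to violations of
them.

## Problem sizes and stochastic-test design

The suite runs at desk scale: 4000-frame trajectories for QSD monitoring
(40 checks at m = 100), 4021-frame shooting ensembles (60 × 67 steps) for
committors, 2000 samples for spectral recovery and CV ranking. Stochastic
comparisons fix their seeds. The "committor error shrinks as the ensemble
doubles" check compares 2000- vs 4000-frame ensembles at a fixed neighbor
count (r adjusted so k = 8 in both) and averages over four seeds; with the
corrected weights both arms already sit near the estimator's noise floor
(RMSE ~0.005–0.01), so the comparison reflects a real ~2× mean improvement
but is inherently a stochastic contrast, not a deterministic invariant.

## Known limitations

- Dense O(n²) memory and O(n³) eigensolves bound practical sample counts to
  ~10⁴; no sparse or Nyström path.
- The QSD rule detects *changes* in the sampled distribution; it cannot
  certify convergence to the QSD, and its thresholds were calibrated on the
  synthetic systems above.
- The `tmd` bandwidth correction uses the ambient (or user-supplied)
  dimension; a misspecified intrinsic dimension reintroduces a drift bias
  on strongly curved manifolds.
- Committor accuracy degrades if the basins are nearly unsampled or the
  kernel graph is close to disconnection; the solver reports rather than
  repairs these conditions.
- The free-energy surface is a visualization aid, not an estimator with
  controlled bias.
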