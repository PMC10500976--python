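"""The synthetic systems and their oracles: samplers, committors, spectra."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
import scipy.integrate
import scipy.linalg
import scipy.stats

from dmapcv import io as dio
from dmapcv import synthetic
from dmapcv.synthetic import (
    analytic_committor_1d,
    barrier_shooting_ensemble,
    empirical_committor,
    fd_committor_1d,
    fd_generator_1d,
    make_fixture_set,
    simulate_langevin,
)


@pytest.mark.parametrize(
    "factory",
    [
        synthetic.double_well_1d,
        synthetic.two_well_2d,
        synthetic.ou_1d,
        synthetic.toy_triatomic,
    ],
)
class TestSystemDefinitions:
    def test_gradient_consistent_with_potential(self, factory):
        system = factory()
        rng = np.random.default_rng(0)
        x = system.references["reactant"] + 0.3 * rng.standard_normal(system.dimension)
        h = 1e-6
        eye = np.eye(system.dimension)
        fd = np.array(
            [
                (system.potential(x + h * eye[i]) - system.potential(x - h * eye[i])) / (2 * h)
                for i in range(system.dimension)
            ]
        )
        np.testing.assert_allclose(system.gradient(x), fd, rtol=1e-5, atol=1e-7)

    def test_references_are_stationary_points(self, factory):
        system = factory()
        for ref in system.references.values():
            assert np.linalg.norm(system.gradient(ref)) < 1e-8


class TestSimulateLangevin:
    def test_frame_count_and_energies(self, double_well):
        res = simulate_langevin(double_well, np.array([0.0]), n_steps=4000, seed=0,
                                include_initial=False)
        assert res.n_frames == 4000
        assert res.energies.shape == (4000,)
        np.testing.assert_allclose(
            res.energies[:5], double_well.potential_batch(res.positions[:5])
        )

    def test_reproducible_under_seed(self, double_well):
        r1 = simulate_langevin(double_well, np.array([1.0]), n_steps=100, seed=42)
        r2 = simulate_langevin(double_well, np.array([1.0]), n_steps=100, seed=42)
        np.testing.assert_array_equal(r1.positions, r2.positions)

    def test_zero_noise_fixed_point(self, double_well):
        res = simulate_langevin(
            double_well, np.array([1.0]), n_steps=200, noise=False, seed=0
        )
        np.testing.assert_allclose(res.positions, 1.0, atol=1e-12)

    def test_ou_stationary_variance(self, ou_system):
        res = simulate_langevin(
            ou_system, np.array([0.0]), dt=1e-3, n_steps=100_000, seed=0, include_initial=False
        )
        expected = 1.0 / (ou_system.beta * ou_system.params["k"])
        assert res.positions.var() == pytest.approx(expected, rel=0.05)

    def test_stability_warning(self, ou_system):
        with pytest.warns(RuntimeWarning, match="stability"):
            simulate_langevin(
                ou_system, np.array([0.0]), dt=1.0, n_steps=1, curvature_hint=2.0
            )

    def test_blow_up_names_step(self, ou_system):
        stiff = synthetic.ou_1d(k=1e6)
        with pytest.raises(FloatingPointError, match="step"), np.errstate(over="ignore"):
            simulate_langevin(stiff, np.array([1.0]), dt=1.0, n_steps=200, seed=0)

    @pytest.mark.parametrize(
        "factory,x0,dt,n_steps,stride,bins",
        [
            (synthetic.ou_1d, [0.0], 5e-3, 400_000, 400, 19),
        ],
    )
    def test_detailed_balance_histogram(self, factory, x0, dt, n_steps, stride, bins):
        """Decorrelated long-run samples match exp(-beta U)/Z (chi-square)."""
        system = factory()
        res = simulate_langevin(
            system, np.array(x0), dt=dt, n_steps=n_steps, seed=0, stride=stride,
            include_initial=False,
        )
        samples = res.positions[:, 0]
        edges = np.linspace(-2.2, 2.2, bins)
        obs, _ = np.histogram(samples, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        w = np.array([np.exp(-system.beta * system.potential(np.array([c]))) for c in centers])
        expected = w / w.sum() * obs.sum()
        mask = expected >= 5
        _, p = scipy.stats.chisquare(
            obs[mask], expected[mask] * obs[mask].sum() / expected[mask].sum()
        )
        assert p > 0.01


class TestBarrierEnsemble:
    def test_single_barrier_frame_then_runs(self, barrier_ensemble, double_well):
        assert barrier_ensemble.n_frames == 1 + 60 * 67
        np.testing.assert_array_equal(
            barrier_ensemble.positions[0], double_well.references["barrier"]
        )
        # the launch configuration appears exactly once
        dup = np.all(barrier_ensemble.positions == 0.0, axis=1)
        assert dup.sum() == 1

    def test_both_basins_visited(self, barrier_ensemble):
        x = barrier_ensemble.positions[:, 0]
        assert (x < -0.5).any() and (x > 0.5).any()


class TestAnalyticCommittor:
    def test_boundaries_and_symmetry(self, double_well):
        q = analytic_committor_1d(double_well, -1.0, 1.0)
        assert q(-1.0) == 0.0
        assert q(1.0) == 1.0
        assert q(0.0) == pytest.approx(0.5, abs=1e-10)
        np.testing.assert_allclose(q(0.3), 1.0 - q(-0.3), atol=1e-8)

    def test_against_independent_riemann_sum(self):
        # tilted double well: compare adaptive quadrature against a dense
        # midpoint Riemann sum implemented from the definition
        h, tilt, beta = 3.0, 0.8, 2.0
        system = synthetic.double_well_1d(h=h, beta=beta)
        tilted = synthetic.SyntheticSystem(
            name="tilted",
            dimension=1,
            potential=lambda x: system.potential(x) + tilt * float(np.asarray(x).reshape(-1)[0]),
            gradient=lambda x: system.gradient(x) + tilt,
            beta=beta,
        )
        q = analytic_committor_1d(tilted, -1.0, 1.0)
        s = np.linspace(-1.0, 1.0, 400_001)
        mids = 0.5 * (s[:-1] + s[1:])
        u = np.array([tilted.potential(np.array([m])) for m in mids])
        w = np.exp(beta * (u - u.max()))
        cdf = np.cumsum(w)
        x = 0.1
        idx = np.searchsorted(mids, x)
        expected = cdf[idx - 1] / cdf[-1]
        assert q(x) == pytest.approx(expected, abs=1e-6)


class TestEmpiricalCommittor:
    A = (np.array([-1.0]), 0.2)
    B = (np.array([1.0]), 0.2)

    def test_point_inside_b_returns_one(self, double_well):
        out = empirical_committor(double_well, np.array([[1.0]]), 10, self.A, self.B, seed=0)
        assert out["q"][0] == 1.0

    def test_barrier_half_within_binomial_error(self, double_well):
        out = empirical_committor(double_well, np.array([[0.0]]), 400, self.A, self.B, seed=1)
        assert abs(out["q"][0] - 0.5) < 3 * out["stderr"][0]

    def test_interior_points_match_analytic(self, double_well):
        # absorbing balls of radius 0.2 around +-1 put the effective
        # boundaries at +-0.8
        q = analytic_committor_1d(double_well, -0.8, 0.8)
        pts = np.linspace(-0.4, 0.4, 20)[:, None]
        out = empirical_committor(double_well, pts, 200, self.A, self.B, seed=5)
        dev = np.abs(out["q"] - q(pts[:, 0])) / out["stderr"]
        assert out["undecided"].sum() == 0
        assert np.max(dev) < 3.0

    def test_overlapping_regions_rejected(self, double_well):
        with pytest.raises(ValueError, match="overlap"):
            empirical_committor(
                double_well, np.zeros((1, 1)), 1, (np.array([0.0]), 1.0), (np.array([1.0]), 1.0)
            )


class TestFiniteDifferenceGenerator:
    def test_null_mode(self, ou_system):
        _, vals, vecs = fd_generator_1d(ou_system, np.linspace(-3, 3, 200))
        assert abs(vals[0]) < 1e-8
        v0 = vecs[:, 0]
        assert np.ptp(v0) < 1e-6 * np.abs(v0).max()

    def test_ou_spectrum_closed_form(self, ou_system):
        """lambda_j = -j k for the harmonic well, within discretization error."""
        _, vals, _ = fd_generator_1d(ou_system, np.linspace(-3, 3, 400))
        k = ou_system.params["k"]
        assert vals[1] == pytest.approx(-k, rel=0.02)
        assert vals[2] == pytest.approx(-2 * k, rel=0.05)

    def test_double_well_metastable_gap(self, double_well):
        _, vals, _ = fd_generator_1d(double_well, np.linspace(-1.8, 1.8, 400))
        # one near-zero metastable mode, then a much faster relaxation mode
        assert abs(vals[1]) < 1e-2
        assert abs(vals[2]) > 100 * abs(vals[1])
        # stable against refining the grid
        _, vals2, _ = fd_generator_1d(double_well, np.linspace(-1.8, 1.8, 800))
        assert vals2[2] == pytest.approx(vals[2], rel=0.02)

    def test_fd_committor_matches_analytic(self, double_well):
        x, qfd = fd_committor_1d(double_well, np.linspace(-1.5, 1.5, 401), -1.0, 1.0)
        qa = analytic_committor_1d(double_well, -1.0, 1.0)
        inner = (x > -1) & (x < 1)
        assert np.max(np.abs(qfd[inner] - qa(x[inner]))) < 1e-3

    def test_nonuniform_grid_rejected(self, ou_system):
        with pytest.raises(ValueError, match="uniform"):
            fd_generator_1d(ou_system, np.array([0.0, 0.1, 0.3, 0.6, 1.0]))


class TestHoppingRunSelection:
    def test_selected_run_has_labeled_clean_hop(self, hop_run):
        run, hop_step, seed = hop_run
        x = run.positions[:, 0]
        assert 1800 <= hop_step <= 3200
        assert x[hop_step] > 0.5
        assert np.all(x[: hop_step - 100] < 0.1)
        # deterministic: the same scan finds the same seed
        _, hop2, seed2 = synthetic.find_hopping_run(seed_start=0)
        assert (hop2, seed2) == (hop_step, seed)


class TestFixtureBundle:
    def test_deterministic_and_readable(self, tmp_path):
        f1 = make_fixture_set(tmp_path / "a", seed=7)
        f2 = make_fixture_set(tmp_path / "b", seed=7)
        digest = lambda p: hashlib.sha256(Path(p).read_bytes()).hexdigest()
        assert all(digest(f1[k]) == digest(f2[k]) for k in f1)
        traj = dio.read_xyz(f1["basin_trajectory"])
        assert traj.energies is not None
        assert traj.element_labels == ["H", "O", "O"]
        manifest = dio.read_yaml(f1["manifest"])
        assert manifest["seed"] == 7

    def test_basin_run_confined_barrier_runs_span(self, tmp_path, triatomic):
        files = make_fixture_set(tmp_path, seed=3)
        topo = dio.read_topology_yaml(files["topology"])
        basin = dio.read_xyz(files["basin_trajectory"])
        from dmapcv.coordinates import compute_internal_coordinates

        ics = compute_internal_coordinates(basin, topo)
        r1 = ics.values[:, 0]
        center = triatomic.params["r1_center"]
        # launched in the short-bond (product) well: never crosses the barrier
        assert np.all(r1 < center)
        shoot = dio.read_xyz(files["barrier_ensemble"])
        r1s = compute_internal_coordinates(shoot, topo).values[:, 0]
        half = triatomic.params["r1_halfwidth"]
        assert (r1s < center - 0.8 * half).any()
        assert (r1s > center + 0.8 * half).any()
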