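"""Quadratic cost assembly, weight solving and the pathway drivers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngeni.errors import GeometryError, ParameterError
from ngeni.fixtures import FixtureSpec, make_pair
from ngeni.metrics import compare_pathways
from ngeni.network import build_cost_network, build_hessian, build_network, compute_modes
from ngeni.pathway import (
    PathwayConfig,
    QuadraticCost,
    assemble_cost,
    exact_cost,
    iteration_count,
    projector,
    run_eni,
    run_ngeni,
    solve_weights,
    target_distances,
)
from ngeni.structures import StructurePair, rmsd


@pytest.fixture(scope="module")
def small_problem():
    """A 12-bead hinge pair with cost network, targets at alpha=0.5 and an
    8-mode basis on the start structure."""
    pair = make_pair(FixtureSpec(kind="hinge", n=12, angle_deg=40))
    cost_net = build_cost_network(pair, 12.0)
    targets = target_distances(pair, cost_net, 0.5)
    nma = build_network(pair.start.coords, 12.0)
    basis = compute_modes(build_hessian(pair.start.coords, nma), 8)
    return pair, cost_net, targets, basis


class TestProjector:
    def test_axis_case(self):
        np.testing.assert_allclose(projector([1.0, 0, 0]), np.diag([0.0, 1.0, 1.0]))

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_projector_properties(self, seed):
        x = np.random.default_rng(seed).normal(size=3) * 4 + 0.1
        a = projector(x)
        np.testing.assert_allclose(a @ x, 0.0, atol=1e-12)
        np.testing.assert_allclose(a @ a, a, atol=1e-12)
        np.testing.assert_allclose(a, a.T, atol=1e-15)
        assert np.trace(a) == pytest.approx(2.0)

    def test_near_zero_vector_raises(self):
        with pytest.raises(GeometryError):
            projector([0.0, 0.0, 1e-12])


class TestTargets:
    def test_endpoint_alphas(self, small_problem):
        pair, net, _, _ = small_problem
        i, j = net.edges[:, 0], net.edges[:, 1]
        t0 = target_distances(pair, net, 0.0)
        np.testing.assert_allclose(
            t0.l, np.linalg.norm(pair.start.coords[i] - pair.start.coords[j], axis=1),
            atol=1e-12,
        )
        t1 = target_distances(pair, net, 1.0)
        np.testing.assert_allclose(
            t1.l, np.linalg.norm(pair.end.coords[i] - pair.end.coords[j], axis=1),
            atol=1e-12,
        )

    def test_midpoint_is_arithmetic_mean(self, small_problem):
        pair, net, _, _ = small_problem
        t0 = target_distances(pair, net, 0.0)
        t1 = target_distances(pair, net, 1.0)
        th = target_distances(pair, net, 0.5)
        np.testing.assert_allclose(th.l, 0.5 * (t0.l + t1.l), atol=1e-12)

    def test_alpha_out_of_range(self, small_problem):
        pair, net, _, _ = small_problem
        with pytest.raises(ParameterError):
            target_distances(pair, net, 1.5)


class TestCostModel:
    def test_quadratic_at_zero_equals_lambda3_equals_exact(self, small_problem):
        pair, net, targets, basis = small_problem
        q = assemble_cost(pair.start, basis, net, targets)
        zero = np.zeros(basis.m)
        assert q.value(zero) == q.lambda3
        assert exact_cost(pair.start, basis, zero, net, targets) == pytest.approx(
            q.lambda3, abs=1e-10
        )

    def test_lambda1_symmetric_lambda3_nonnegative(self, small_problem):
        pair, net, targets, basis = small_problem
        q = assemble_cost(pair.start, basis, net, targets)
        np.testing.assert_allclose(q.lambda1, q.lambda1.T, atol=1e-10)
        assert q.lambda3 >= 0

    def test_gradient_matches_finite_differences_of_exact_cost(self, small_problem):
        """The model gradient at C_w = 0 (half lambda2) must equal central
        finite differences of the exact cost along each mode direction."""
        pair, net, targets, basis = small_problem
        q = assemble_cost(pair.start, basis, net, targets)
        h = 1e-4
        fd = np.empty(basis.m)
        for k in range(basis.m):
            e = np.zeros(basis.m)
            e[k] = h
            fd[k] = (
                exact_cost(pair.start, basis, e, net, targets)
                - exact_cost(pair.start, basis, -e, net, targets)
            ) / (2 * h)
        model = 0.5 * q.lambda2
        assert np.abs(fd - model).max() / np.abs(fd).max() < 1e-5

    def test_satisfied_targets_zero_linear_and_constant_terms(self, small_problem):
        pair, net, _, basis = small_problem
        current = target_distances(pair, net, 0.0)  # l_ij = start distances
        q = assemble_cost(pair.start, basis, net, current)
        assert q.lambda3 == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(q.lambda2, 0.0, atol=1e-10)

    def test_taylor_model_valid_at_solved_step(self, small_problem):
        pair, net, targets, basis = small_problem
        # one-step targets (alpha = 1/s) keep the displacement small
        t = target_distances(pair, net, 1.0 / 24)
        q = assemble_cost(pair.start, basis, net, t)
        w = solve_weights(q)
        approx = q.value(w.c)
        exact = exact_cost(pair.start, basis, w.c, net, t)
        assert abs(exact - approx) / max(exact, 1e-12) < 0.05


class TestSolveWeights:
    def test_zero_linear_term_gives_zero_weights(self):
        q = QuadraticCost(lambda1=np.diag([2.0, 3.0]), lambda2=np.zeros(2), lambda3=1.0)
        np.testing.assert_array_equal(solve_weights(q).c, 0.0)

    def test_scalar_closed_form(self):
        a, b = 3.0, 4.0
        q = QuadraticCost(lambda1=np.array([[a]]), lambda2=np.array([b]), lambda3=0.0)
        assert solve_weights(q).c[0] == pytest.approx(-b / (2 * a))

    def test_solution_beats_random_search(self):
        rng = np.random.default_rng(7)
        m = 5
        root = rng.normal(size=(m, m))
        q = QuadraticCost(
            lambda1=root @ root.T + np.eye(m), lambda2=rng.normal(size=m), lambda3=2.0
        )
        c_star = solve_weights(q).c
        best = q.value(c_star)
        norm = np.linalg.norm(c_star)
        for _ in range(1000):
            trial = rng.normal(size=m)
            trial *= norm / np.linalg.norm(trial)
            assert q.value(trial) >= best - 1e-12

    def test_singular_lambda1_falls_back_to_least_squares(self):
        q = QuadraticCost(
            lambda1=np.array([[1.0, 0.0], [0.0, 0.0]]),
            lambda2=np.array([2.0, 0.0]),
            lambda3=0.0,
        )
        w = solve_weights(q)
        assert np.all(np.isfinite(w.c))
        assert q.value(w.c) <= q.value(np.zeros(2))

    def test_never_increases_quadratic_for_indefinite_system(self):
        q = QuadraticCost(
            lambda1=np.diag([1.0, -2.0]), lambda2=np.array([1.0, 0.5]), lambda3=5.0
        )
        w = solve_weights(q)
        assert q.value(w.c) <= q.value(np.zeros(2)) + 1e-12


class TestIterationRule:
    @pytest.mark.parametrize(
        "value,expected",
        [(7.1, 71), (15.4, 154), (3.4, 34), (5.5, 55), (0.0, 0)],
    )
    def test_step_count_is_ten_times_rmsd(self, value, expected):
        assert iteration_count(value) == expected


class TestDrivers:
    def test_identical_endpoints_give_trivial_pathway(self, helix20):
        pair = StructurePair(start=helix20, end=helix20.with_coords(helix20.coords))
        p = run_ngeni(pair)
        assert len(p.conformations) == 1
        assert p.s == 0
        assert p.final_residual == pytest.approx(0.0, abs=1e-12)

    def test_pathway_shape_and_start_identity(self, hinge_pair):
        p = run_ngeni(hinge_pair, PathwayConfig(modes=10, steps=6))
        assert len(p.conformations) == 7  # start + s computed steps
        np.testing.assert_array_equal(p.conformations[0].coords, hinge_pair.start.coords)
        assert [r.alpha for r in p.records] == pytest.approx(
            [k / 6 for k in range(1, 7)]
        )

    def test_full_mode_ngeni_equals_eni_per_coordinate(self, hinge_pair):
        pn = run_ngeni(hinge_pair, PathwayConfig(modes="full"))
        pe = run_eni(hinge_pair, PathwayConfig())
        assert len(pn.conformations) == len(pe.conformations)
        for a, b in zip(pn.conformations, pe.conformations):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-6)

    def test_full_mode_recovery_and_monotone_approach(self, hinge_pair):
        p = run_ngeni(hinge_pair, PathwayConfig(modes="full"))
        assert p.final_residual < 0.1
        assert p.monotone_violations() == []

    def test_mode_count_nestedness_final_residual(self, hinge_pair):
        r30 = run_ngeni(hinge_pair, PathwayConfig(modes=30)).final_residual
        r5 = run_ngeni(hinge_pair, PathwayConfig(modes=5)).final_residual
        assert r30 <= r5

    def test_reverse_pathway_returns_to_start(self, hinge_pair):
        p = run_ngeni(hinge_pair.reversed(), PathwayConfig(modes="full"))
        assert rmsd(p.last_computed(), hinge_pair.start) < 0.1

    def test_deterministic_given_config(self, hinge_pair):
        cfg = PathwayConfig(modes=10, steps=5)
        p1 = run_ngeni(hinge_pair, cfg)
        p2 = run_ngeni(hinge_pair, cfg)
        for a, b in zip(p1.conformations, p2.conformations):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_eni_reverse_and_trivial(self, hinge_pair, helix20):
        trivial = StructurePair(start=helix20, end=helix20.with_coords(helix20.coords))
        assert run_eni(trivial).s == 0
        rev = run_eni(hinge_pair.reversed(), PathwayConfig())
        assert rmsd(rev.last_computed(), hinge_pair.start) < 0.1

    def test_safeguarded_run_matches_contract(self, hinge_pair):
        p = run_ngeni(hinge_pair, PathwayConfig(modes="full", safeguard=True))
        assert p.final_residual < 0.1
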