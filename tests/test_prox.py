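"""Projection operators, gradient/divergence pair, and the primal-dual solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from ctuq.prox import (
    BallConstraint,
    LinearOp,
    SolverConfig,
    div2d,
    grad2d,
    grad_operator,
    identity_operator,
    mask_operator,
    masked_grad_operator,
    primal_dual_solve,
    project_l1_ball,
    project_l2_ball,
    project_nonneg,
)


def l1_ball_oracle(x: np.ndarray, radius: float) -> np.ndarray:
    """Exhaustive KKT breakpoint scan for the l1-ball projection (small n)."""
    if np.abs(x).sum() <= radius:
        return x.copy()
    v = np.abs(x)
    # optimal theta makes sum(max(v - theta, 0)) == radius; scan breakpoints
    breaks = np.sort(np.concatenate([[0.0], v]))
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        # on (lo, hi] the active set is fixed; solve linearly for theta
        active = v > lo
        theta = (v[active].sum() - radius) / active.sum()
        if lo <= theta <= hi:
            return np.sign(x) * np.maximum(v - theta, 0.0)
    theta = (v.sum() - radius) / v.size
    return np.sign(x) * np.maximum(v - theta, 0.0)


class TestProjections:
    def test_nonneg_basic(self):
        x = np.array([-1.0, 2.0])
        np.testing.assert_array_equal(project_nonneg(x), [0.0, 2.0])
        y = np.array([0.5, 1.0])
        np.testing.assert_array_equal(project_nonneg(y), y)

    def test_nonneg_optimality_brute(self, rng):
        x = rng.standard_normal(20)
        p = project_nonneg(x)
        d = np.linalg.norm(p - x)
        for _ in range(100):
            z = rng.uniform(0, 3, size=20)
            assert d <= np.linalg.norm(z - x) + 1e-12

    def test_l2_ball_inside_and_radial(self, rng):
        c = rng.standard_normal(10)
        u = rng.standard_normal(10)
        u /= np.linalg.norm(u)
        inside = c + 0.5 * u
        np.testing.assert_allclose(project_l2_ball(inside, c, 1.0), inside)
        outside = c + 2.0 * u
        np.testing.assert_allclose(project_l2_ball(outside, c, 1.0), c + u,
                                   atol=1e-12)

    def test_l2_ball_optimality_sampling(self, rng):
        c = rng.standard_normal(8)
        x = c + rng.standard_normal(8) * 3
        r = 1.3
        p = project_l2_ball(x, c, r)
        d = np.linalg.norm(p - x)
        for _ in range(1000):
            z = rng.standard_normal(8)
            z = c + z / max(np.linalg.norm(z), 1e-12) * r * rng.uniform()
            assert d <= np.linalg.norm(z - x) + 1e-10

    def test_l1_ball_trivial_cases(self):
        x = np.array([0.3, -0.2])
        np.testing.assert_array_equal(project_l1_ball(x, 1.0), x)
        np.testing.assert_allclose(project_l1_ball(np.array([3.0, 0.0]), 1.0),
                                   [1.0, 0.0])

    @given(
        arrays(float, st.integers(1, 5),
               elements=st.floats(-5, 5, allow_nan=False)),
        st.floats(0.01, 4.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_l1_ball_matches_breakpoint_oracle(self, x, radius):
        got = project_l1_ball(x, radius)
        want = l1_ball_oracle(x, radius)
        np.testing.assert_allclose(got, want, atol=1e-9)
        assert np.abs(got).sum() <= radius + 1e-9

    @pytest.mark.parametrize("proj", [
        project_nonneg,
        lambda x: project_l2_ball(x, np.zeros(12), 1.0),
        lambda x: project_l1_ball(x, 1.0),
    ], ids=["nonneg", "l2ball", "l1ball"])
    def test_idempotent_and_nonexpansive(self, proj, rng):
        for _ in range(50):
            u = rng.standard_normal(12) * 2
            v = rng.standard_normal(12) * 2
            pu, pv = proj(u), proj(v)
            np.testing.assert_allclose(proj(pu), pu, atol=1e-10)
            assert np.linalg.norm(pu - pv) <= np.linalg.norm(u - v) + 1e-10


class TestGrad:
    def test_constant_image_zero_field(self):
        assert not grad2d(np.full((6, 7), 3.2)).any()

    def test_column_ramp_closed_form(self):
        x = np.tile(np.arange(5.0), (4, 1))
        g = grad2d(x)
        assert not g[0].any()
        np.testing.assert_array_equal(g[1][:, :-1], 1.0)
        np.testing.assert_array_equal(g[1][:, -1], 0.0)

    def test_adjoint_identity_with_divergence(self, rng):
        x = rng.standard_normal((8, 8))
        p = rng.standard_normal((2, 8, 8))
        lhs = np.vdot(grad2d(x), p)
        rhs = np.vdot(x, -div2d(p))
        assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)

    @pytest.mark.parametrize("make_op", [
        lambda: grad_operator((9, 7)),
        lambda: mask_operator(np.eye(8, dtype=bool)),
        lambda: masked_grad_operator(np.eye(8, dtype=bool)),
    ], ids=["grad", "mask", "masked_grad"])
    def test_operator_adjoints_and_norm_bounds(self, make_op, rng):
        op = make_op()
        assert op.adjoint_test(seed=3) <= 1e-12
        est = op.estimate_norm(seed=3)
        assert op.norm_bound >= est * (1 - 1e-6)
        x = rng.standard_normal(op.in_shape)
        assert np.linalg.norm(op.fwd(x)) <= op.norm_bound * np.linalg.norm(x) + 1e-9


class TestSolver:
    def test_converges_to_l2_projection(self, rng):
        # min 1/2||x - x0||^2 s.t. x in B(c, r) has the ball projection as
        # its unique solution
        c = rng.standard_normal((6, 6))
        r = 0.7
        x0 = c + rng.standard_normal((6, 6)) * 4
        op = identity_operator((6, 6))
        x, diag = primal_dual_solve(
            [(op, BallConstraint(center=c, radius=r, name="ball"))],
            init=x0, config=SolverConfig(max_iters=5000, step_balance=1.0),
            grad_f=lambda z: z - x0, lipschitz_f=1.0,
        )
        assert diag.converged
        np.testing.assert_allclose(x, project_l2_ball(x0, c, r), atol=5e-3)

    def test_pure_feasibility_returns_feasible_point(self, rng):
        # with f = 0 every feasible point is optimal; the solver must land
        # in the constraint set
        c = rng.standard_normal((6, 6))
        x0 = c + rng.standard_normal((6, 6)) * 4
        op = identity_operator((6, 6))
        x, diag = primal_dual_solve(
            [(op, BallConstraint(center=c, radius=0.7, name="ball"))],
            init=x0, config=SolverConfig(max_iters=5000, step_balance=1.0),
        )
        assert diag.converged
        assert np.linalg.norm(x - c) <= 0.7 * (1 + 1e-4)

    def test_feasible_init_is_fixed_point(self, rng):
        c = rng.standard_normal((5, 5))
        x0 = c.copy()
        op = identity_operator((5, 5))
        x, diag = primal_dual_solve(
            [(op, BallConstraint(center=c, radius=2.0, name="ball"))],
            init=x0, config=SolverConfig(max_iters=2000, step_balance=1.0),
        )
        assert diag.converged
        np.testing.assert_allclose(x, x0, atol=1e-6)

    def test_smooth_plus_nonneg_closed_form(self, rng):
        a = rng.standard_normal((7, 7)) * 2
        op = identity_operator((7, 7))
        x, diag = primal_dual_solve(
            [(op, BallConstraint(center=np.zeros((7, 7)), radius=100.0,
                                 name="loose"))],
            init=np.zeros((7, 7)),
            config=SolverConfig(max_iters=5000, step_balance=1.0),
            grad_f=lambda z: z - a, lipschitz_f=1.0,
            prox_g=project_nonneg,
        )
        assert diag.converged
        np.testing.assert_allclose(x, np.maximum(a, 0.0), atol=1e-4)

    def test_operator_application_counts_are_exact(self):
        calls = {"fwd": 0, "adj": 0}

        def fwd(x):
            calls["fwd"] += 1
            return x

        def adj(u):
            calls["adj"] += 1
            return u

        op = LinearOp(fwd, adj, in_shape=(4, 4), out_shape=(4, 4),
                      norm_bound=1.0, name="counted")
        c = np.zeros((4, 4))
        primal_dual_solve(
            [(op, BallConstraint(center=c, radius=1.0, name="ball"))],
            init=np.ones((4, 4)) * 5,
            config=SolverConfig(max_iters=500, step_balance=1.0),
        )
        assert op.n_forward == calls["fwd"]
        assert op.n_adjoint == calls["adj"]
        assert op.n_applications == calls["fwd"] + calls["adj"]

    def test_nonconvergence_is_flagged(self, rng):
        # infeasible problem: two disjoint balls on the same variable
        op = identity_operator((3, 3))
        c1 = np.zeros((3, 3))
        c2 = np.full((3, 3), 10.0)
        x, diag = primal_dual_solve(
            [(op, BallConstraint(center=c1, radius=0.5, name="b1")),
             (identity_operator((3, 3)), BallConstraint(center=c2, radius=0.5,
                                                        name="b2"))],
            init=rng.standard_normal((3, 3)),
            config=SolverConfig(max_iters=300, step_balance=1.0),
        )
        assert not diag.converged
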