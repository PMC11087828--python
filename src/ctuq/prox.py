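"""Projections, linear operators and a Condat-Vu primal-dual solver.

Both optimisation problems of the pipeline -- the sparsity-constrained MAP
reconstruction and the set-distance computation of the hypothesis test -- are
instances of

    minimize  f(x) + g(x) + sum_i h_i(L_i x)

with f smooth (possibly zero), g a simple projection (nonnegativity), and each
h_i either the indicator of a closed convex set or the l1 norm, composed with
a linear operator L_i.  The solver dualises every h_i via the Moreau identity,
so it only ever needs projections and operator applications; forward/adjoint
applications of every operator are counted exactly, which is the
hardware-independent cost unit used by the cost-accounting diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LinearOp",
    "SolverConfig",
    "Diagnostics",
    "DualTerm",
    "BallConstraint",
    "L1BallConstraint",
    "L1Norm",
    "project_nonneg",
    "project_l2_ball",
    "project_l1_ball",
    "grad2d",
    "div2d",
    "grad_operator",
    "identity_operator",
    "mask_operator",
    "masked_grad_operator",
    "component_operator",
    "primal_dual_solve",
]


# ---------------------------------------------------------------------------
# linear operators


class LinearOp:
    """A linear map with its adjoint, a norm bound, and application counters."""

    def __init__(
        self,
        forward: Callable[[np.ndarray], np.ndarray],
        adjoint: Callable[[np.ndarray], np.ndarray],
        *,
        in_shape: tuple,
        out_shape: tuple,
        norm_bound: float | None = None,
        name: str = "",
    ) -> None:
        self._forward = forward
        self._adjoint = adjoint
        self.in_shape = tuple(in_shape)
        self.out_shape = tuple(out_shape)
        self.norm_bound = norm_bound
        self.name = name
        self.n_forward = 0
        self.n_adjoint = 0

    def fwd(self, x: np.ndarray) -> np.ndarray:
        self.n_forward += 1
        return self._forward(x)

    def adj(self, u: np.ndarray) -> np.ndarray:
        self.n_adjoint += 1
        return self._adjoint(u)

    @property
    def n_applications(self) -> int:
        """Total forward plus adjoint applications so far."""
        return self.n_forward + self.n_adjoint

    def estimate_norm(self, n_iter: int = 50, seed: int = 0) -> float:
        """Operator-norm estimate by power iteration on L^T L (not counted)."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.in_shape)
        x /= np.linalg.norm(x)
        est = 0.0
        for _ in range(n_iter):
            y = self._adjoint(self._forward(x))
            nrm = np.linalg.norm(y)
            if nrm == 0:
                return 0.0
            est = np.sqrt(nrm)
            x = y / nrm
        return float(est)

    def adjoint_test(self, seed: int = 0) -> float:
        """Relative discrepancy |<Lx,u> - <x,L^T u>| / (|Lx||u|) on a probe."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.in_shape)
        u = rng.standard_normal(self.out_shape)
        lx = self._forward(x)
        ltu = self._adjoint(u)
        a = float(np.vdot(lx, u))
        b = float(np.vdot(x, ltu))
        scale = max(np.linalg.norm(lx) * np.linalg.norm(u), 1e-300)
        return abs(a - b) / scale


def identity_operator(shape: tuple, name: str = "I") -> LinearOp:
    return LinearOp(
        lambda x: x, lambda u: u, in_shape=shape, out_shape=shape,
        norm_bound=1.0, name=name,
    )


def mask_operator(mask: np.ndarray, name: str = "M") -> LinearOp:
    """Pixel-selection operator M: image -> vector of the masked pixels."""
    mask = np.asarray(mask, dtype=bool)
    ns = int(mask.sum())
    if ns == 0:
        raise ValueError("mask is empty")

    def fwd(x: np.ndarray) -> np.ndarray:
        return x[mask]

    def adj(v: np.ndarray) -> np.ndarray:
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    return LinearOp(fwd, adj, in_shape=mask.shape, out_shape=(ns,),
                    norm_bound=1.0, name=name)


def grad2d(x: np.ndarray) -> np.ndarray:
    """Forward finite differences with replicate (Neumann) boundary.

    Returns a 2-channel field: channel 0 is the vertical (row) difference,
    channel 1 the horizontal (column) difference; the last difference along
    each axis is zero.
    """
    g = np.zeros((2,) + x.shape)
    g[0, :-1, :] = x[1:, :] - x[:-1, :]
    g[1, :, :-1] = x[:, 1:] - x[:, :-1]
    return g


def div2d(g: np.ndarray) -> np.ndarray:
    """Negative adjoint of grad2d (a discrete divergence)."""
    out = np.zeros(g.shape[1:])
    out[:-1, :] += g[0, :-1, :]
    out[1:, :] -= g[0, :-1, :]
    out[:, :-1] += g[1, :, :-1]
    out[:, 1:] -= g[1, :, :-1]
    return out


def grad_operator(shape: tuple, name: str = "grad") -> LinearOp:
    # ||grad||^2 <= 8 for forward differences in 2D
    return LinearOp(
        grad2d, lambda g: -div2d(g), in_shape=shape, out_shape=(2,) + shape,
        norm_bound=float(np.sqrt(8.0)), name=name,
    )


def masked_grad_operator(mask: np.ndarray, name: str = "Mgrad") -> LinearOp:
    """M o grad: gradient computed globally, then restricted to mask pixels."""
    mask = np.asarray(mask, dtype=bool)
    ns = int(mask.sum())
    if ns == 0:
        raise ValueError("mask is empty")

    def fwd(x: np.ndarray) -> np.ndarray:
        g = grad2d(x)
        return np.concatenate([g[0][mask], g[1][mask]])

    def adj(v: np.ndarray) -> np.ndarray:
        g = np.zeros((2,) + mask.shape)
        g[0][mask] = v[:ns]
        g[1][mask] = v[ns:]
        return -div2d(g)

    return LinearOp(fwd, adj, in_shape=mask.shape, out_shape=(2 * ns,),
                    norm_bound=float(np.sqrt(8.0)), name=name)


def component_operator(inner: LinearOp, index: int, n_slots: int = 2) -> LinearOp:
    """Lift an operator to act on one slot of a stacked variable.

    Used for the product-space formulation of the set-distance problem, where
    the primal variable stacks (x_S, x_C) along a leading axis.
    """

    def fwd(z: np.ndarray) -> np.ndarray:
        return inner.fwd(z[index])

    def adj(u: np.ndarray) -> np.ndarray:
        out = np.zeros((n_slots,) + inner.in_shape)
        out[index] = inner.adj(u)
        return out

    op = LinearOp(
        fwd, adj, in_shape=(n_slots,) + inner.in_shape,
        out_shape=inner.out_shape, norm_bound=inner.norm_bound,
        name=f"{inner.name}[{index}]",
    )
    return op


# ---------------------------------------------------------------------------
# projections


def project_nonneg(x: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the nonnegative orthant."""
    return np.maximum(x, 0.0)


def project_l2_ball(x: np.ndarray, center: np.ndarray | float, radius: float) -> np.ndarray:
    """Euclidean projection onto the closed l2 ball B(center, radius)."""
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    d = x - center
    nrm = float(np.linalg.norm(d))
    if nrm <= radius:
        return x.copy() if isinstance(x, np.ndarray) else x
    return center + d * (radius / nrm)


def project_l1_ball(x: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto {z : ||z||_1 <= radius} by sort-and-threshold.

    Stable sort so ties between equal-magnitude entries are broken
    deterministically.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    shape = x.shape
    v = np.abs(x).ravel()
    if v.sum() <= radius:
        return x.copy()
    if radius == 0:
        return np.zeros(shape)
    u = np.sort(v, kind="stable")[::-1]
    css = np.cumsum(u)
    k = np.arange(1, u.size + 1)
    rho = np.nonzero(u * k > (css - radius))[0][-1]
    theta = (css[rho] - radius) / (rho + 1.0)
    out = np.sign(x.ravel()) * np.maximum(v - theta, 0.0)
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# dual terms


class DualTerm:
    """A term h_i(L_i x) handled in the dual via the Moreau identity.

    ``step_weight`` scales this term's dual step in the step-size budget:
    terms whose constraint is loose at the optimum can take a smaller weight,
    freeing a larger primal step.
    """

    name = "term"
    step_weight = 1.0

    def moreau_dual_prox(self, v: np.ndarray, sigma: float) -> np.ndarray:
        raise NotImplementedError

    def residual(self, lx: np.ndarray) -> float | None:
        """Absolute distance of L x to the constraint set (None if not a set)."""
        return None

    def scale(self) -> float:
        """Characteristic scale used to normalise the residual."""
        return 1.0


@dataclass
class BallConstraint(DualTerm):
    """Indicator of the closed l2 ball {u : ||u - center||_2 <= radius}."""

    center: np.ndarray | float
    radius: float
    name: str = "l2ball"
    step_weight: float = 1.0

    def moreau_dual_prox(self, v: np.ndarray, sigma: float) -> np.ndarray:
        return v - sigma * project_l2_ball(v / sigma, self.center, self.radius)

    def residual(self, lx: np.ndarray) -> float:
        d = float(np.linalg.norm(lx - self.center))
        return max(d - self.radius, 0.0)

    def scale(self) -> float:
        c = float(np.linalg.norm(np.asarray(self.center, dtype=float)))
        return max(self.radius, c, 1e-12)


@dataclass
class L1BallConstraint(DualTerm):
    """Indicator of {u : ||u||_1 <= radius}."""

    radius: float
    name: str = "l1ball"
    step_weight: float = 1.0

    def moreau_dual_prox(self, v: np.ndarray, sigma: float) -> np.ndarray:
        return v - sigma * project_l1_ball(v / sigma, self.radius)

    def residual(self, lx: np.ndarray) -> float:
        return max(float(np.abs(lx).sum()) - self.radius, 0.0)

    def scale(self) -> float:
        return max(self.radius, 1e-12)


@dataclass
class L1Norm(DualTerm):
    """The l1 norm as an objective term; its dual prox is the l-inf clip."""

    weight: float = 1.0
    name: str = "l1"
    step_weight: float = 1.0

    def moreau_dual_prox(self, v: np.ndarray, sigma: float) -> np.ndarray:
        return np.clip(v, -self.weight, self.weight)

    def value(self, lx: np.ndarray) -> float:
        return float(self.weight * np.abs(lx).sum())


# ---------------------------------------------------------------------------
# solver


@dataclass
class SolverConfig:
    """Primal-dual solver settings.

    ``tol_primal`` is the per-iteration relative change of the iterate
    (measured as the change over one check window divided by the window
    length); ``tol_feas`` bounds every constraint's distance-to-set relative
    to the set's scale.  ``step_scale`` in (0, 1) is the safety factor in the
    Condat-Vu step-size inequality.
    """

    max_iters: int = 20000
    tol_primal: float = 1e-5
    tol_feas: float = 1e-4
    step_scale: float = 0.99
    step_balance: float = 1.0
    check_every: int = 25
    min_iters: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.step_scale < 1):
            raise ValueError("step_scale must be in (0, 1)")
        if self.tol_primal <= 0 or self.tol_feas <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Diagnostics:
    """Per-run solver diagnostics, including exact operator application counts."""

    iterations: int = 0
    converged: bool = False
    rel_change: float = np.inf
    feas_residuals: dict = field(default_factory=dict)
    history: list = field(default_factory=list)
    op_applications: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return list(self.history)


def primal_dual_solve(
    terms: Sequence[tuple[LinearOp, DualTerm]],
    init: np.ndarray,
    config: SolverConfig | None = None,
    *,
    grad_f: Callable[[np.ndarray], np.ndarray] | None = None,
    lipschitz_f: float = 0.0,
    prox_g: Callable[[np.ndarray], np.ndarray] | None = None,
    stat_fn: Callable[[np.ndarray], float] | None = None,
    stat_scale: float = 1.0,
) -> tuple[np.ndarray, Diagnostics]:
    """Condat-Vu primal-dual iteration for f(x) + g(x) + sum_i h_i(L_i x).

    Every h_i is dualised; the primal step handles the smooth gradient and the
    simple prox g.  Steps tau, sigma satisfy
    1/tau - sigma * sum_i ||L_i||^2 >= lipschitz_f / 2 with a safety margin.

    When ``stat_fn`` is given (e.g. the achieved set distance), the stability
    half of the stopping rule tracks that statistic (relative to
    ``stat_scale``) instead of the full iterate: the run stops when every
    constraint is satisfied and the estimate of record has stopped moving.

    Returns the final iterate and diagnostics; non-convergence within
    ``max_iters`` is flagged, never silent.
    """
    config = config or SolverConfig()
    x = np.array(init, dtype=float, copy=True)

    bound_sq = 0.0
    for op, _ in terms:
        if op.norm_bound is None:
            op.norm_bound = 1.01 * op.estimate_norm()
        bound_sq += op.norm_bound**2
    # per-term dual steps sigma_i = theta / ||L_i|| keep every constraint's
    # dual equally strong regardless of operator scale; the Condat-Vu
    # inequality 1/tau - sum_i sigma_i ||L_i||^2 >= L_f/2 then fixes tau
    theta = config.step_balance
    bounds = [op.norm_bound for op, _ in terms]
    weights = [getattr(term, "step_weight", 1.0) for _, term in terms]
    weighted_sum = sum(w * b for w, b in zip(weights, bounds))
    if weighted_sum > 0:
        sigmas = [theta * w / max(b, 1e-12) for w, b in zip(weights, bounds)]
        tau = config.step_scale / (lipschitz_f / 2.0 + theta * weighted_sum)
    else:
        sigmas = [1.0 for _ in terms]
        tau = config.step_scale / max(lipschitz_f, 1.0)


    start_counts = {id(op): op.n_applications for op, _ in terms}
    duals = [np.zeros(op.out_shape) for op, _ in terms]

    diag = Diagnostics()
    x_prev_check = x.copy()
    stat_prev = np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        z = np.zeros_like(x)
        for (op, _), u in zip(terms, duals):
            z += op.adj(u)
        if grad_f is not None:
            z += grad_f(x)
        x_new = x - tau * z
        if prox_g is not None:
            x_new = prox_g(x_new)
        xb = 2.0 * x_new - x
        for i, (op, term) in enumerate(terms):
            v = duals[i] + sigmas[i] * op.fwd(xb)
            duals[i] = term.moreau_dual_prox(v, sigmas[i])
        x = x_new

        if it % config.check_every == 0 and it >= config.min_iters:
            denom = max(float(np.linalg.norm(x)), 1e-12)
            rel = float(np.linalg.norm(x - x_prev_check)) / denom / config.check_every
            x_prev_check = x.copy()
            feas = {}
            feas_ok = True
            for op, term in terms:
                r = term.residual(op.fwd(x))
                if r is None:
                    continue
                rel_r = r / term.scale()
                feas[term.name] = rel_r
                feas_ok &= rel_r <= config.tol_feas
            diag.rel_change = rel
            diag.feas_residuals = feas
            row = {"iteration": it, "rel_change": rel, **feas}
            if stat_fn is not None:
                # stability of the tracked statistic replaces stability of
                # the full iterate (the statistic is the estimate of record)
                stat = float(stat_fn(x))
                row["stat"] = stat
                stat_change = abs(stat - stat_prev) / max(stat_scale, 1e-12)
                stat_prev = stat
                stable = stat_change / config.check_every <= config.tol_primal
            else:
                stable = rel <= config.tol_primal
            diag.history.append(row)
            if stable and feas_ok:
                converged = True
                break

    diag.iterations = it
    diag.converged = converged
    diag.op_applications = {
        (op.name or f"op{i}"): op.n_applications - start_counts[id(op)]
        for i, (op, _) in enumerate(terms)
    }
    return x, diag
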