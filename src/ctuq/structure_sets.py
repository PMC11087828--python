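"""The two convex sets of the hypothesis test.

* The conservative credible region
  ``C_alpha = {x >= 0 : ||Phi x - y||_2 <= eps, ||Psi x||_1 <= eta_alpha}``
  built around the MAP estimate; its l1 budget ``eta_alpha`` follows the
  concentration bound ``||Psi x_dagger||_1 + N + sqrt(16 N log(3/alpha))``.

* The structure-absent set ``S = I ∩ E ∩ S`` — nonnegativity, an energy ball
  keeping the masked pixels near the neighbourhood's median intensity, and a
  smoothness ball keeping the masked gradient field near the neighbourhood's
  median gradient magnitude.  The ball parameters (mu_pix, r_pix, mu_grad,
  r_grad) are chosen automatically from histograms of the MAP estimate over a
  dilation annulus around the mask: mu is the median, r the larger of
  (P60 - median) and (median - P40).

The per-pixel tolerances r_pix / r_grad act as RMS tolerances: the ball radii
scale with the square root of the number of constrained components, and the
smoothness radius includes mu_grad so the set always contains a flat patch
(whose signed gradient components sit at zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from . import ct_model
from .ct_model import Geometry, Sinogram
from .map_recon import PsiSpec, psi_operator
from .prox import (
    BallConstraint,
    SolverConfig,
    Diagnostics,
    grad2d,
    mask_operator,
    masked_grad_operator,
    primal_dual_solve,
    project_nonneg,
)

__all__ = [
    "CredibleRegion",
    "StructureSet",
    "compute_eta_alpha",
    "build_structure_set",
    "membership",
    "project_structure_set",
]


@dataclass
class CredibleRegion:
    """Conservative posterior credible region around the MAP estimate."""

    y: Sinogram
    epsilon: float
    eta_alpha: float
    alpha: float
    psi: PsiSpec
    geometry: Geometry

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.epsilon < 0 or self.eta_alpha < 0:
            raise ValueError("radii must be nonnegative")


@dataclass
class StructureSet:
    """Structure-absent set parameters for one candidate region."""

    mask: np.ndarray
    neighborhood: np.ndarray
    mu_pix: float
    r_pix: float
    mu_grad: float
    r_grad: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.neighborhood = np.asarray(self.neighborhood, dtype=bool)
        if not self.mask.any() or not self.neighborhood.any():
            raise ValueError("mask and neighborhood must be nonempty")
        if (self.mask & self.neighborhood).any():
            raise ValueError("mask and neighborhood must be disjoint")
        if self.r_pix < 0 or self.r_grad < 0:
            raise ValueError("radii must be nonnegative")

    @property
    def n_structure(self) -> int:
        """Number of pixels in the candidate structure (NS)."""
        return int(self.mask.sum())

    # effective l2-ball radii: per-pixel tolerances as RMS tolerances
    @property
    def r_pix_eff(self) -> float:
        return self.r_pix * float(np.sqrt(self.n_structure))

    @property
    def r_grad_eff(self) -> float:
        if np.isinf(self.r_grad):
            return np.inf
        return (self.r_grad + self.mu_grad) * float(np.sqrt(2 * self.n_structure))


def compute_eta_alpha(
    psi_l1_of_map: float,
    n_pixels: int,
    alpha: float,
    reading: Literal["sqrt", "verbatim"] = "sqrt",
) -> float:
    """l1 budget of the conservative credible region.

    Default reading: ``||Psi x_dagger||_1 + N + sqrt(16 N log(3/alpha))``
    (the tau*sqrt(N) concentration scaling); ``reading='verbatim'`` uses
    ``||Psi x_dagger||_1 + N + 16 N log(3/alpha)`` instead.  Strictly
    decreasing in alpha and never below ``psi_l1 + N``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    log_term = np.log(3.0 / alpha)
    if reading == "sqrt":
        slack = np.sqrt(16.0 * n_pixels * log_term)
    elif reading == "verbatim":
        slack = 16.0 * n_pixels * log_term
    else:
        raise ValueError(f"unknown reading: {reading!r}")
    return float(psi_l1_of_map + n_pixels + slack)


def _percentile_radius(samples: np.ndarray) -> tuple[float, float]:
    """Median and max(P60 - median, median - P40), linear interpolation."""
    med = float(np.median(samples))
    p60 = float(np.percentile(samples, 60))
    p40 = float(np.percentile(samples, 40))
    return med, max(p60 - med, med - p40)


def build_structure_set(
    x_dagger: np.ndarray,
    mask: np.ndarray,
    dilation_width: int = 3,
    valid: np.ndarray | None = None,
) -> StructureSet:
    """Derive the structure-absent set from the MAP estimate's neighbourhood.

    The neighbourhood is the annulus (mask dilated by ``dilation_width``)
    minus the mask, optionally intersected with ``valid`` (e.g. a body mask).
    Intensity statistics are taken from ``x_dagger`` over the annulus; the
    gradient statistics use the per-pixel Euclidean magnitude of the
    forward-difference field.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    dilated = ndimage.binary_dilation(mask, iterations=int(dilation_width))
    neighborhood = dilated & ~mask
    if valid is not None:
        neighborhood &= np.asarray(valid, dtype=bool)
    if not neighborhood.any():
        raise ValueError("neighborhood annulus is empty")

    mu_pix, r_pix = _percentile_radius(x_dagger[neighborhood])
    g = grad2d(x_dagger)
    grad_mag = np.sqrt(g[0] ** 2 + g[1] ** 2)
    mu_grad, r_grad = _percentile_radius(grad_mag[neighborhood])
    return StructureSet(
        mask=mask, neighborhood=neighborhood,
        mu_pix=mu_pix, r_pix=r_pix, mu_grad=mu_grad, r_grad=r_grad,
    )


def _credible_constraints(region: CredibleRegion):
    """The two dualised constraints of C_alpha (nonnegativity is primal)."""
    phi = ct_model.radon_operator(region.geometry)
    psi_op = psi_operator(
        region.psi, (region.geometry.image_side, region.geometry.image_side)
    )
    from .prox import L1BallConstraint

    return [
        (phi, BallConstraint(center=region.y.values, radius=region.epsilon,
                             name="data")),
        (psi_op, L1BallConstraint(radius=region.eta_alpha, name="psi_budget")),
    ], phi


def _structure_constraints(s: StructureSet):
    ns = s.n_structure
    terms = [
        (mask_operator(s.mask, name="M"),
         BallConstraint(center=np.full(ns, s.mu_pix), radius=s.r_pix_eff,
                        name="energy")),
    ]
    if not np.isinf(s.r_grad_eff):
        terms.append(
            (masked_grad_operator(s.mask, name="Mgrad"),
             BallConstraint(center=np.full(2 * ns, s.mu_grad),
                            radius=s.r_grad_eff, name="smoothness"))
        )
    return terms


def membership(
    x: np.ndarray,
    region: CredibleRegion | StructureSet,
    tol: float = 1e-4,
) -> tuple[bool, dict[str, float]]:
    """Check whether ``x`` belongs to the region within a relative tolerance.

    Returns the verdict and each constraint's relative violation magnitude.
    """
    viol: dict[str, float] = {}
    scale = max(float(np.abs(x).max()), 1e-12)
    viol["nonneg"] = max(0.0, -float(x.min())) / scale

    if isinstance(region, CredibleRegion):
        terms, _ = _credible_constraints(region)
    else:
        terms = _structure_constraints(region)
    for op, term in terms:
        r = term.residual(op._forward(x))
        viol[term.name] = r / term.scale()
    return all(v <= tol for v in viol.values()), viol


def project_structure_set(
    x: np.ndarray,
    s: StructureSet,
    config: SolverConfig | None = None,
) -> tuple[np.ndarray, Diagnostics]:
    """Euclidean projection of ``x`` onto S = I ∩ E ∩ S.

    Solved by the primal-dual iteration with the smooth term
    ``f = 1/2 ||. - x||^2``; only the mask and its gradient stencil support
    are affected (other pixels already satisfy every constraint and stay at
    their input values up to solver tolerance).
    """
    config = config or SolverConfig()
    x = np.asarray(x, dtype=float)
    terms = _structure_constraints(s)
    out, diag = primal_dual_solve(
        terms,
        init=x,
        config=config,
        grad_f=lambda z: z - x,
        lipschitz_f=1.0,
        prox_g=project_nonneg,
    )
    return out, diag
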