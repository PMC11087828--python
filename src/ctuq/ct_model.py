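"""Parallel-beam CT measurement model.

The forward operator is a pixel-driven discrete Radon transform assembled as a
sparse matrix, so its adjoint is the exact matrix transpose.  Each pixel centre
is projected onto the (unit-spaced, image-centred) detector axis of every view
and its value is splatted onto the two nearest detector bins with linear
weights; with detector spacing equal to the pixel spacing the row sums
approximate line integrals through the image.

Measurements follow ``y = Phi x + w`` with ``w`` i.i.d. zero-mean Gaussian.
The data-fidelity radius ``epsilon`` is the chi-square quantile bound on
``||w||_2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .prox import LinearOp

__all__ = [
    "Geometry",
    "Sinogram",
    "radon_matrix",
    "radon_operator",
    "radon_forward",
    "radon_adjoint",
    "simulate_measurements",
    "epsilon_bound",
]


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    Parameters
    ----------
    n_angles : int
        Number of projection angles ``Ma``; angles are equispaced over
        ``[0, pi)``.
    n_detectors : int
        Number of detector bins ``D`` per view, spacing 1 pixel, centred on
        the image centre.
    image_side : int
        Side length of the (square) reconstruction grid, in pixels.
    """

    n_angles: int
    n_detectors: int
    image_side: int

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_detectors < 1 or self.image_side < 2:
            raise ValueError(
                f"invalid geometry: Ma={self.n_angles}, D={self.n_detectors}, "
                f"side={self.image_side}"
            )

    @property
    def angles(self) -> np.ndarray:
        """Projection angles in radians, strictly increasing in [0, pi)."""
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def m_meas(self) -> int:
        """Total measurement dimension Ma * D."""
        return self.n_angles * self.n_detectors

    @property
    def n_pixels(self) -> int:
        return self.image_side * self.image_side


@dataclass
class Sinogram:
    """A stack of line-integral measurements, one row per angle."""

    values: np.ndarray
    geometry: Geometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))


_MATRIX_CACHE: dict[Geometry, sp.csr_matrix] = {}


def radon_matrix(geometry: Geometry) -> sp.csr_matrix:
    """Assemble (and cache) the sparse system matrix of shape (Ma*D, N).

    Image coordinates: (row, col) from the top-left, 0-based.  A pixel at
    (r, c) has centred coordinates x = c - (side-1)/2 (to the right) and
    y = (side-1)/2 - r (upwards); a view at angle theta measures the signed
    detector coordinate t = x cos(theta) + y sin(theta).
    """
    cached = _MATRIX_CACHE.get(geometry)
    if cached is not None:
        return cached

    side = geometry.image_side
    d = geometry.n_detectors
    n = geometry.n_pixels
    half = (side - 1) / 2.0
    rows_grid, cols_grid = np.meshgrid(
        np.arange(side), np.arange(side), indexing="ij"
    )
    x = (cols_grid - half).ravel()
    y = (half - rows_grid).ravel()
    pix = np.arange(n)

    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    for a, theta in enumerate(geometry.angles):
        t = x * np.cos(theta) + y * np.sin(theta) + (d - 1) / 2.0
        i0 = np.floor(t).astype(np.int64)
        w1 = t - i0
        for bins, weights in ((i0, 1.0 - w1), (i0 + 1, w1)):
            ok = (bins >= 0) & (bins < d) & (weights > 0)
            rows_out.append(a * d + bins[ok])
            cols_out.append(pix[ok])
            vals_out.append(weights[ok])

    mat = sp.csr_matrix(
        (
            np.concatenate(vals_out),
            (np.concatenate(rows_out), np.concatenate(cols_out)),
        ),
        shape=(geometry.m_meas, n),
    )
    if len(_MATRIX_CACHE) > 8:
        _MATRIX_CACHE.clear()
    _MATRIX_CACHE[geometry] = mat
    return mat


_OPERATOR_CACHE: dict[Geometry, LinearOp] = {}


def radon_operator(geometry: Geometry) -> LinearOp:
    """The forward operator Phi as a counted LinearOp (image -> sinogram).

    One shared instance per geometry, so forward/adjoint application counts
    accumulate consistently across the pipeline stages that use it.
    """
    cached = _OPERATOR_CACHE.get(geometry)
    if cached is not None:
        return cached
    mat = radon_matrix(geometry)
    mat_t = mat.T.tocsr()
    shape_img = (geometry.image_side, geometry.image_side)
    shape_sino = (geometry.n_angles, geometry.n_detectors)

    def fwd(img: np.ndarray) -> np.ndarray:
        return (mat @ img.ravel()).reshape(shape_sino)

    def adj(sino: np.ndarray) -> np.ndarray:
        return (mat_t @ sino.ravel()).reshape(shape_img)

    op = LinearOp(fwd, adj, in_shape=shape_img, out_shape=shape_sino, name="Phi")
    op.norm_bound = 1.01 * op.estimate_norm(seed=0)
    if len(_OPERATOR_CACHE) > 8:
        _OPERATOR_CACHE.clear()
    _OPERATOR_CACHE[geometry] = op
    return op


def radon_forward(image: np.ndarray, geometry: Geometry) -> Sinogram:
    """Apply Phi to an image, returning the sinogram."""
    image = np.asarray(image, dtype=float)
    if image.shape != (geometry.image_side, geometry.image_side):
        raise ValueError(
            f"image shape {image.shape} does not match geometry side "
            f"{geometry.image_side}"
        )
    mat = radon_matrix(geometry)
    vals = (mat @ image.ravel()).reshape(geometry.n_angles, geometry.n_detectors)
    return Sinogram(vals, geometry)


def radon_adjoint(sinogram: Sinogram) -> np.ndarray:
    """Apply the exact adjoint Phi^T (backprojection) to a sinogram."""
    g = sinogram.geometry
    mat = radon_matrix(g)
    return (mat.T @ sinogram.values.ravel()).reshape(g.image_side, g.image_side)


def simulate_measurements(
    image: np.ndarray, geometry: Geometry, sigma: float, seed: int
) -> Sinogram:
    """Simulate ``y = Phi x + w`` with i.i.d. Gaussian noise of std ``sigma``.

    ``sigma`` is in sinogram units (callers emulating acquisition-quality
    regimes express it as a fraction of the noiseless sinogram maximum and
    convert before calling).  Deterministic for a fixed seed.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    clean = radon_forward(image, geometry)
    if sigma == 0:
        return clean
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=clean.values.shape)
    return Sinogram(clean.values + noise, geometry)


def epsilon_bound(sigma: float, m_meas: int, quantile: float = 0.99) -> float:
    """Radius eps with P(||w||_2 <= eps) = quantile for w ~ N(0, sigma^2 I_m).

    This is sigma * sqrt(chi2.ppf(quantile, m_meas)); it makes the l2-ball
    data constraint feasible with probability ``quantile``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if m_meas < 1:
        raise ValueError("m_meas must be >= 1")
    if sigma == 0:
        return 0.0
    return float(sigma * np.sqrt(stats.chi2.ppf(quantile, df=m_meas)))
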