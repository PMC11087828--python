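"""Synthetic thorax-like phantoms and reproducible test scenarios.

The generator emulates a contrast-enhanced axial chest slice at the level of
the pulmonary arteries: a soft-tissue body ellipse, two darker lung fields,
bright contrast-filled vessels inside the lungs, and optional pulmonary-
embolism-like inserts — compact darker regions inside a vessel, the classic
filling-defect appearance.  Ground-truth masks for every insert are recorded,
so scenarios can state whether a probed region is a real structure or not.

Two canned scenario builders mirror the study conditions:

* ``make_pe_scenario`` — a structure-present case probing a true insert under
  a chosen (number of angles, noise level) acquisition.
* ``make_artifact_scenario`` — a structure-absent case: a low-quality
  acquisition (50 angles, noise at 0.175 of the sinogram maximum) whose MAP
  reconstruction shows a compact locally dark blob where no insert exists;
  the probe mask is auto-detected as a black-top-hat intensity dip inside a
  vessel that is confirmed absent from the ground truth.

Noise levels are expressed as a fraction of the noiseless sinogram's maximum
absolute value, so the acquisition-quality regimes transfer across phantom
scales; ``Scenario.sigma`` stores the resulting absolute value in sinogram
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from . import ct_model
from .ct_model import Geometry
from .map_recon import MapResult, PsiSpec, map_estimate
from .prox import SolverConfig

__all__ = [
    "Truth",
    "Phantom",
    "Scenario",
    "generate_thorax_phantom",
    "make_pe_scenario",
    "make_artifact_scenario",
    "REFERENCE_DETECTORS",
]

REFERENCE_DETECTORS = 450  # detector count of the reference acquisition grid

_BODY_VALUE = 0.30
_LUNG_VALUE = 0.10
_VESSEL_VALUE = 0.90


class Truth(str, Enum):
    STRUCTURE_PRESENT = "STRUCTURE_PRESENT"
    STRUCTURE_ABSENT = "STRUCTURE_ABSENT"


@dataclass
class Phantom:
    image: np.ndarray
    pe_masks: list[np.ndarray]
    background_label: np.ndarray  # vessel/lumen regions
    seed: int
    vessels: list[tuple[tuple[float, float], float]] = field(default_factory=list)

    @property
    def side(self) -> int:
        return self.image.shape[0]


@dataclass
class Scenario:
    phantom: Phantom
    geometry: Geometry
    sigma: float  # absolute, sinogram units
    sigma_frac: float
    probe_mask: np.ndarray
    truth: Truth
    seed: int
    noise_seed: int
    cache: dict = field(default_factory=dict, repr=False)


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + (
        (cc - center[1]) / semi_axes[1]
    ) ** 2 <= 1.0


def generate_thorax_phantom(
    side_length: int = 128,
    n_vessels: int = 4,
    pe_specs: list[tuple[tuple[float, float], float, float]] | None = None,
    seed: int = 0,
) -> Phantom:
    """Generate a thorax-like phantom with optional PE-like inserts.

    ``pe_specs`` is a list of ((row, col), radius, contrast) triples; each
    insert must be a disc of radius >= 2 lying entirely inside a vessel and
    its value is ``vessel_value * (1 - contrast)``, i.e. a darker filling
    defect.  Deterministic for a fixed seed.
    """
    if side_length < 32:
        raise ValueError("side_length must be >= 32")
    pe_specs = list(pe_specs or [])
    rng = np.random.default_rng(seed)
    shape = (side_length, side_length)
    s = side_length

    image = np.zeros(shape)
    body = _ellipse(shape, (s / 2, s / 2), (0.40 * s, 0.46 * s))
    image[body] = _BODY_VALUE
    lungs = []
    for sign in (-1, 1):
        lung = _ellipse(
            shape,
            (s / 2 + 0.02 * s * rng.uniform(-1, 1), s / 2 + sign * 0.22 * s),
            (0.28 * s, 0.17 * s),
        )
        lung &= body
        image[lung] = _LUNG_VALUE
        lungs.append(lung)
    lung_union = lungs[0] | lungs[1]

    # bright contrast-filled vessels, placed well inside the lung fields
    vessel_mask = np.zeros(shape, dtype=bool)
    vessels: list[tuple[tuple[float, float], float]] = []
    interior = ndimage.binary_erosion(lung_union, iterations=max(2, s // 24))
    candidates = np.argwhere(interior)
    order = rng.permutation(len(candidates))
    for idx in order:
        if len(vessels) >= n_vessels:
            break
        center = candidates[idx]
        radius = rng.uniform(0.055, 0.085) * s
        disc = _disc(shape, tuple(center), radius)
        if not disc.any():
            continue
        if not (disc & ~interior).any() and not (disc & vessel_mask).any():
            level = _VESSEL_VALUE * rng.uniform(0.95, 1.0)
            image[disc] = level
            vessel_mask |= disc
            vessels.append(((float(center[0]), float(center[1])), radius))
    if len(vessels) < n_vessels:
        # deterministic fallback: fixed offsets inside each lung
        for k in range(n_vessels - len(vessels)):
            lung = lungs[k % 2]
            rows, cols = np.nonzero(ndimage.binary_erosion(lung, iterations=s // 16))
            if len(rows) == 0:
                continue
            c = (float(rows[len(rows) // 2]), float(cols[len(cols) // 2]))
            disc = _disc(shape, c, 0.05 * s)
            image[disc] = _VESSEL_VALUE
            vessel_mask |= disc
            vessels.append((c, 0.05 * s))

    pe_masks: list[np.ndarray] = []
    for center, radius, contrast in pe_specs:
        if radius < 2:
            raise ValueError(f"PE radius must be >= 2 pixels, got {radius}")
        if not 0 < contrast <= 1:
            raise ValueError(f"PE contrast must be in (0, 1], got {contrast}")
        disc = _disc(shape, center, radius)
        if not disc.any():
            raise ValueError(f"PE insert at {center} lies outside the image")
        if (disc & ~vessel_mask).any():
            raise ValueError(
                f"PE insert at {center} (radius {radius}) is not fully inside "
                "a vessel region"
            )
        vessel_level = float(np.median(image[disc]))
        image[disc] = vessel_level * (1.0 - contrast)
        pe_masks.append(disc)

    return Phantom(image=image, pe_masks=pe_masks,
                   background_label=vessel_mask, seed=seed, vessels=vessels)


def _auto_pe_spec(phantom_seed: int, side: int, contrast: float) -> tuple:
    """A PE spec concentric with the largest vessel of the seeded phantom.

    A concentric disc of strictly smaller radius is always contained in the
    rasterised vessel disc, so the insert is valid by construction.
    """
    base = generate_thorax_phantom(side, seed=phantom_seed)
    if not base.vessels:
        raise RuntimeError("phantom has no vessel regions")
    center, radius = max(base.vessels, key=lambda v: v[1])
    return (center, max(2.0, 0.45 * radius), contrast)


def sigma_absolute(image: np.ndarray, geometry: Geometry, sigma_frac: float) -> float:
    """Convert a fractional noise level to sinogram units."""
    clean = ct_model.radon_forward(image, geometry)
    return float(sigma_frac * np.abs(clean.values).max())


def make_pe_scenario(
    ma: int,
    sigma: float,
    seed: int,
    *,
    side: int = 128,
    n_detectors: int = REFERENCE_DETECTORS,
    pe_contrast: float = 0.6,
) -> Scenario:
    """Structure-present scenario probing a true PE-like insert.

    The phantom depends on the seed only, so scenarios at different
    acquisition settings share the same ground truth.
    """
    if ma < 10:
        raise ValueError("ma must be >= 10")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    spec = _auto_pe_spec(seed, side, pe_contrast)
    phantom = generate_thorax_phantom(side, pe_specs=[spec], seed=seed)
    geometry = Geometry(n_angles=ma, n_detectors=n_detectors, image_side=side)
    sigma_abs = sigma_absolute(phantom.image, geometry, sigma)
    return Scenario(
        phantom=phantom,
        geometry=geometry,
        sigma=sigma_abs,
        sigma_frac=sigma,
        probe_mask=phantom.pe_masks[0],
        truth=Truth.STRUCTURE_PRESENT,
        seed=seed,
        noise_seed=(seed * 9973 + 17) % (2**31),
    )


def make_artifact_scenario(
    seed: int,
    *,
    side: int = 128,
    ma: int = 50,
    sigma: float = 0.175,
    n_detectors: int | None = None,
    dip_threshold: float = 0.03,
    tophat_radius: int = 5,
    darkness_margin: float = 0.02,
    deficit_threshold: float = 0.1,
    min_area: int = 3,
    max_area: int | None = None,
    max_tries: int = 12,
    psi: PsiSpec = PsiSpec("wavelet", "db4", 3),
    solver_config: SolverConfig | None = None,
    quantile: float = 0.99,
) -> Scenario:
    """Structure-absent scenario: probe a PE-like reconstruction artifact.

    The phantom has no inserts; the low-quality acquisition (defaults: 50
    angles, noise 0.175 of the sinogram maximum) is reconstructed with a
    wavelet sparsity prior, which at this quality hallucinates compact dark
    blobs inside vessels (a TV prior over-smooths them away at these sizes).
    Candidate probes are local intensity dips — black-top-hat response above
    ``dip_threshold`` inside the eroded vessel interior — that are (a)
    locally dark: mean intensity at least ``darkness_margin`` below the
    surrounding annulus of the reconstruction, and (b) absent from the
    ground truth: mean truth-minus-reconstruction deficit above
    ``deficit_threshold``.  The largest qualifying blob becomes the probe
    mask.  If no blob qualifies, further derived phantom seeds are tried;
    exhausting ``max_tries`` raises with a diagnostic.

    The simulated sinogram and the MAP result are cached on the returned
    Scenario so downstream runs need not recompute them.
    """
    if n_detectors is None:
        n_detectors = side
    if max_area is None:
        max_area = (side // 8) ** 2
    geometry = Geometry(n_angles=ma, n_detectors=n_detectors, image_side=side)
    footprint = morphology.disk(tophat_radius)
    last_diag = "no attempts made"
    for trial in range(max_tries):
        ph_seed = (seed + trial * 7919) % (2**31)
        phantom = generate_thorax_phantom(side, seed=ph_seed)
        sigma_abs = sigma_absolute(phantom.image, geometry, sigma)
        noise_seed = (ph_seed * 9973 + 17) % (2**31)
        y = ct_model.simulate_measurements(
            phantom.image, geometry, sigma_abs, noise_seed
        )
        eps = ct_model.epsilon_bound(sigma_abs, geometry.m_meas, quantile)
        map_res = map_estimate(y, geometry, psi, eps, solver_config)

        x_map = map_res.x_dagger
        interior = ndimage.binary_erosion(phantom.background_label, iterations=2)
        dips = morphology.black_tophat(x_map, footprint=footprint)
        blobs = measure.label((dips > dip_threshold) & interior)
        best = None
        for prop in measure.regionprops(blobs):
            if not min_area <= prop.area <= max_area:
                continue
            blob = blobs == prop.label
            annulus = ndimage.binary_dilation(blob, iterations=3) & ~blob
            locally_dark = (x_map[blob].mean()
                            <= x_map[annulus].mean() - darkness_margin)
            true_deficit = (phantom.image - x_map)[blob].mean()
            if not locally_dark or true_deficit <= deficit_threshold:
                continue
            if best is None or prop.area > best.area:
                best = prop
        if best is None:
            last_diag = (
                f"trial {trial}: no locally dark dip above {dip_threshold} "
                f"with area in [{min_area}, {max_area}]"
            )
            continue
        probe = blobs == best.label
        scenario = Scenario(
            phantom=phantom,
            geometry=geometry,
            sigma=sigma_abs,
            sigma_frac=sigma,
            probe_mask=probe,
            truth=Truth.STRUCTURE_ABSENT,
            seed=ph_seed,
            noise_seed=noise_seed,
        )
        scenario.cache = {
            "sinogram": y,
            "map_result": map_res,
            "psi": psi,
            "quantile": quantile,
            "epsilon": eps,
        }
        return scenario
    raise RuntimeError(
        f"could not find a PE-like artifact after {max_tries} tries ({last_diag})"
    )
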