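"""DAB/hematoxylin stain separation and membrane segmentation.

Brightfield IHC images are modelled with the Beer-Lambert law: each pixel's
per-channel optical density ``OD_c = -log10((I_c + eps) / 255)`` is a
non-negative linear combination of stain-specific unit vectors
(hematoxylin counterstain, brown DAB chromogen, and a residual axis).
Inverting that mixture recovers per-stain density maps.  Stained cell
membranes appear as thin curvilinear DAB ridges; a Hessian-based ridge
filter at the membrane scale enhances them, and a bimodal (Otsu) threshold
on the ridge response, combined with a DAB optical-density floor, yields
the binary membrane mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import filters

from .config import ConfigError, InputError, DEFAULT_DAB_OD, DEFAULT_HEMATOXYLIN_OD

logger = logging.getLogger(__name__)

#: intensity offset avoiding log(0) on fully absorbing pixels
OD_EPS = 1.0


@dataclass
class SpotImage:
    """One RGB brightfield image of a TMA spot plus its physical scale.

    ``pixels`` is an H×W×3 array of intensities in [0, 255] (8-bit, or
    float for synthetic images rendered without quantization); ``mpp`` is
    the pixel pitch in microns per pixel.
    """

    pixels: np.ndarray
    mpp: float
    spot_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InputError(
                f"spot image must be H×W×3 RGB, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InputError("spot image must contain at least one pixel")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise InputError("channel values must lie in [0, 255]")
        if self.mpp <= 0:
            raise InputError(f"mpp must be positive, got {self.mpp}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class StainMap:
    """Per-pixel optical densities of the two stains of an H-DAB image."""

    dab_od: np.ndarray
    hema_od: np.ndarray

    def __post_init__(self) -> None:
        if self.dab_od.shape != self.hema_od.shape:
            raise InputError("stain planes must share dimensions")


@dataclass
class MembraneMask:
    """Binary mask of DAB-stained membrane pixels.

    An all-false mask is meaningful: no detectable membrane staining.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def _stain_matrix(
    stain_vectors: tuple | None,
) -> np.ndarray:
    """3×3 OD mixing matrix with unit-norm columns (hema, DAB, residual)."""
    if stain_vectors is None:
        stain_vectors = (DEFAULT_HEMATOXYLIN_OD, DEFAULT_DAB_OD)
    vecs = [np.asarray(v, dtype=float) for v in stain_vectors]
    if any(v.shape != (3,) for v in vecs):
        raise ConfigError("stain vectors must have three components each")
    vecs = [v / np.linalg.norm(v) for v in vecs]
    if len(vecs) == 2:
        residual = np.cross(vecs[0], vecs[1])
        norm = np.linalg.norm(residual)
        if norm < 1e-8:
            raise ConfigError("stain vectors are collinear")
        vecs.append(residual / norm)
    elif len(vecs) != 3:
        raise ConfigError("expected 2 or 3 stain vectors")
    matrix = np.stack(vecs, axis=1)
    if abs(np.linalg.det(matrix)) < 1e-8:
        raise ConfigError("stain matrix is singular")
    return matrix


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Per-channel optical density of RGB intensities in [0, 255]."""
    return -np.log10((np.asarray(pixels, dtype=float) + OD_EPS) / 255.0)


def rgb_to_stain_od(
    image: SpotImage,
    stain_vectors: tuple | None = None,
) -> StainMap:
    """Decompose an RGB image into hematoxylin and DAB density maps.

    Per-pixel optical densities are projected onto the stain basis by
    solving the linear mixture; negative coefficients (noise outside the
    physical cone of the basis) are clipped to zero, so a pure-white pixel
    maps to zero density in both stains.
    """
    matrix = _stain_matrix(stain_vectors)
    od = rgb_to_od(image.pixels)
    flat = od.reshape(-1, 3)
    conc = np.linalg.solve(matrix, flat.T).T
    conc = np.clip(conc, 0.0, None)
    h, w = image.shape
    return StainMap(
        dab_od=conc[:, 1].reshape(h, w),
        hema_od=conc[:, 0].reshape(h, w),
    )


def od_to_rgb(
    hema_od: np.ndarray,
    dab_od: np.ndarray,
    stain_vectors: tuple | None = None,
    quantize: bool = True,
) -> np.ndarray:
    """Forward Beer-Lambert rendering of stain densities to RGB.

    The exact inverse of :func:`rgb_to_stain_od` when ``quantize`` is
    False; with ``quantize`` the result is rounded to 8-bit intensities.
    """
    matrix = _stain_matrix(stain_vectors)
    hema_od = np.asarray(hema_od, dtype=float)
    dab_od = np.asarray(dab_od, dtype=float)
    od = hema_od[..., None] * matrix[:, 0] + dab_od[..., None] * matrix[:, 1]
    rgb = 255.0 * np.exp(-od * np.log(10.0)) - OD_EPS
    rgb = np.clip(rgb, 0.0, 255.0)
    if quantize:
        return np.round(rgb).astype(np.uint8)
    return rgb


def linear_structure_response(
    stain: StainMap,
    scale_um: float = 1.0,
    mpp: float = 0.25,
) -> np.ndarray:
    """Enhance curvilinear DAB structures of width ~``scale_um``.

    A single-scale Sato (Hessian-eigenvalue) ridge measure on the DAB
    density plane: high along bright lines, suppressed on isotropic blobs
    and flat regions, identically zero on constant input, and invariant to
    adding a constant density.
    """
    if scale_um <= 0:
        raise InputError("scale_um must be positive")
    sigma_px = scale_um / mpp
    if sigma_px < 1.0:
        logger.warning(
            "ridge scale %.3g um is below one pixel at %.3g um/px; clamping",
            scale_um,
            mpp,
        )
        sigma_px = 1.0
    dab = np.asarray(stain.dab_od, dtype=float)
    if np.ptp(dab) == 0:
        return np.zeros_like(dab)
    response = filters.sato(dab, sigmas=[sigma_px], black_ridges=False, mode="reflect")
    return np.clip(response, 0.0, None)


def segment_membrane(
    response: np.ndarray,
    stain: StainMap,
    min_dab_od: float = 0.15,
) -> MembraneMask:
    """Bimodal segmentation of the ridge response into a membrane mask.

    A single global Otsu threshold is chosen from the histogram of
    positive ridge responses; a pixel is membrane when its response
    reaches that threshold *and* its DAB density reaches ``min_dab_od``
    (keeping chromogen-free ridges out of the mask).  A degenerate
    (single-mode) response histogram yields an empty mask.
    """
    response = np.asarray(response, dtype=float)
    if response.shape != stain.dab_od.shape:
        raise InputError("response and stain maps must share dimensions")
    candidates = response[response > 0]
    if candidates.size < 2 or np.ptp(candidates) == 0:
        logger.info("degenerate ridge-response histogram; empty membrane mask")
        return MembraneMask(np.zeros(response.shape, dtype=bool))
    threshold = filters.threshold_otsu(candidates)
    mask = (response >= threshold) & (stain.dab_od >= min_dab_od)
    return MembraneMask(mask)
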