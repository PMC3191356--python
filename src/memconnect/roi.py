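"""Region-of-interest definition and the per-spot analysis pipeline.

Tissue is detected as pixels whose total optical density clears a floor
(glass background is bright and nearly density-free), holes are filled and
dust specks removed.  The ROI is the tissue mask eroded so that every ROI
pixel lies at least ``margin_px`` from the nearest tissue edge — guarding
against edge-staining artifacts — and a spot is only analyzed when its ROI
area strictly exceeds a minimum (default 37,000 µm², about 5% of the ROI
of an intact 1-mm spot).  Spots flagged as manually excluded (inadequate
tumour sample, DCIS) are never processed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .config import RunConfig
from .connectivity import ConnectivityParams, ConnectivityResult, compute_connectivity
from .stains import (
    MembraneMask,
    SpotImage,
    linear_structure_response,
    rgb_to_od,
    rgb_to_stain_od,
)

logger = logging.getLogger(__name__)

STATUS_ANALYZED = "analyzed"
STATUS_EXCLUDED_AREA = "excluded_area"
STATUS_EXCLUDED_MANUAL = "excluded_manual"


@dataclass
class RoiMask:
    """Analyzed region of a spot with its physical area and adequacy."""

    mask: np.ndarray
    area_um2: float
    adequate: bool = False


@dataclass
class SpotResult:
    """Outcome of the digital analysis of one TMA spot."""

    spot_id: str
    patient_id: str
    roi: Optional[RoiMask]
    connectivity_result: Optional[ConnectivityResult]
    status: str
    exclude_reason: str = ""


def detect_tissue(
    image: SpotImage,
    od_floor: float = 0.1,
    min_speck_px: int = 100,
) -> np.ndarray:
    """Binary tissue mask: total-OD floor, hole filling, speck removal."""
    total_od = np.clip(rgb_to_od(image.pixels), 0.0, None).sum(axis=2)
    mask = total_od > od_floor
    if not mask.any():
        return mask
    mask = ndi.binary_fill_holes(mask)
    # components strictly smaller than min_speck_px are dust
    return morphology.remove_small_objects(mask, max_size=min_speck_px - 1)


def apply_margin(
    tissue_mask: np.ndarray,
    margin_px: int = 100,
    mpp: float = 0.25,
) -> RoiMask:
    """Erode the tissue mask so every ROI pixel is >= margin_px from the edge."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if margin_px < 0:
        raise ValueError("margin_px must be non-negative")
    if margin_px == 0 or not tissue_mask.any():
        roi = tissue_mask
    else:
        distance = ndi.distance_transform_edt(tissue_mask)
        roi = tissue_mask & (distance >= margin_px)
    return RoiMask(mask=roi, area_um2=float(roi.sum()) * mpp**2)


def area_control(roi: RoiMask, min_roi_area_um2: float = 37_000.0) -> bool:
    """Adequacy rule: the ROI area must strictly exceed the minimum."""
    roi.adequate = roi.area_um2 > min_roi_area_um2
    return roi.adequate


def analyze_spot(
    image: SpotImage,
    config: RunConfig | None = None,
    manual_exclude: bool = False,
    exclude_reason: str = "",
) -> SpotResult:
    """Run the full digital analysis of one spot image.

    Order of operations: manual-exclusion flag, tissue detection, edge
    margin, area control, stain separation, ridge enhancement, bimodal
    segmentation restricted to the ROI, skeletonization/merging/pruning,
    connectivity and HER2 score.  Deterministic for a given image and
    configuration.
    """
    config = config or RunConfig()
    if manual_exclude:
        return SpotResult(
            spot_id=image.spot_id,
            patient_id=image.patient_id,
            roi=None,
            connectivity_result=None,
            status=STATUS_EXCLUDED_MANUAL,
            exclude_reason=exclude_reason or "manual exclusion",
        )
    tissue = detect_tissue(image, config.tissue_od_floor, config.min_speck_px)
    roi = apply_margin(tissue, config.margin_px, image.mpp)
    if not area_control(roi, config.min_roi_area_um2):
        return SpotResult(
            spot_id=image.spot_id,
            patient_id=image.patient_id,
            roi=roi,
            connectivity_result=None,
            status=STATUS_EXCLUDED_AREA,
            exclude_reason=f"ROI area {roi.area_um2:.0f} um2 <= {config.min_roi_area_um2:.0f} um2",
        )
    stain = rgb_to_stain_od(image, (config.hema_od_vector, config.dab_od_vector))
    response = linear_structure_response(stain, config.ridge_scale_um, image.mpp)
    membrane = segment_in_roi(response, stain, roi, config.min_dab_od)
    params = ConnectivityParams(
        c_low=config.c_low,
        c_high=config.c_high,
        gap_px=config.gap_px,
        min_fragment_px=config.min_fragment_px,
    )
    result = compute_connectivity(
        membrane, params, config.score_t_low, config.score_t_high
    )
    return SpotResult(
        spot_id=image.spot_id,
        patient_id=image.patient_id,
        roi=roi,
        connectivity_result=result,
        status=STATUS_ANALYZED,
    )


def segment_in_roi(response, stain, roi: RoiMask, min_dab_od: float) -> MembraneMask:
    """Membrane segmentation restricted to the region of interest."""
    from .stains import segment_membrane

    membrane = segment_membrane(response, stain, min_dab_od)
    membrane.mask &= roi.mask
    return membrane


def load_spot_image(
    path: str | Path,
    mpp: float = 0.25,
    spot_id: str = "",
    patient_id: str = "",
) -> SpotImage:
    """Read an 8-bit RGB TIFF or PNG spot image from disk."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SpotImage(pixels=pixels, mpp=mpp, spot_id=spot_id or path.stem, patient_id=patient_id)


def spot_result_row(result: SpotResult) -> dict:
    """Flatten a SpotResult to one output-CSV row."""
    row = {
        "spot_id": result.spot_id,
        "patient_id": result.patient_id,
        "status": result.status,
        "exclude_reason": result.exclude_reason,
        "roi_area_um2": result.roi.area_um2 if result.roi is not None else np.nan,
        "n_fragments": np.nan,
        "total_skeleton_px": np.nan,
        "connectivity": np.nan,
        "her2_score": "",
    }
    if result.connectivity_result is not None:
        cr = result.connectivity_result
        row.update(
            n_fragments=cr.n_fragments,
            total_skeleton_px=cr.total_skeleton_px,
            connectivity=round(cr.connectivity, 6),
            her2_score=cr.her2_score,
        )
    return row


def analyze_batch(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Analyze every spot of a manifest, continuing past per-spot errors.

    Manifest columns: spot_id, patient_id, image_path, and optionally
    mpp (defaults to the config value), manual_exclude (0/1) and
    exclude_reason.
    """
    config = config or RunConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    rows = []
    for rec in manifest.to_dict("records"):
        spot_id = str(rec.get("spot_id", ""))
        try:
            image = load_spot_image(
                rec["image_path"],
                mpp=float(rec.get("mpp", config.mpp) or config.mpp),
                spot_id=spot_id,
                patient_id=str(rec.get("patient_id", "")),
            )
            result = analyze_spot(
                image,
                config,
                manual_exclude=bool(int(rec.get("manual_exclude", 0) or 0)),
                exclude_reason=str(rec.get("exclude_reason", "") or ""),
            )
            rows.append(spot_result_row(result))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("spot %s failed: %s", spot_id, exc)
            rows.append(
                {
                    "spot_id": spot_id,
                    "patient_id": str(rec.get("patient_id", "")),
                    "status": "error",
                    "exclude_reason": str(exc),
                }
            )
    return pd.DataFrame(rows)
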