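"""Run configuration shared by the whole analysis pipeline.

Every tunable of the digital-analysis pipeline lives in a single
:class:`RunConfig` so that a run can be reproduced from its logged
configuration alone.  The defaults encode the published operating point of
the method: HER2 score cut-points at connectivity 0.12 and 0.56, a 100-pixel
edge margin on the region of interest, a 37,000 µm² minimum ROI area, and a
pixel pitch of 0.25 µm/px (100 px ≈ 25 µm at 20× brightfield scanning).
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration values."""


class InputError(ValueError):
    """Raised for invalid data handed to an analysis operation."""


# Ruifrok-Johnston optical-density unit vectors for hematoxylin and DAB.
DEFAULT_HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
DEFAULT_DAB_OD = (0.269, 0.568, 0.778)


@dataclass
class RunConfig:
    """All tunables of the spot-analysis pipeline, with defaults.

    Attributes
    ----------
    mpp:
        Microns per pixel of the input image (default 0.25; can be
        overridden per image from the manifest).
    margin_px:
        Euclidean distance (pixels) from the ROI to the nearest tissue
        edge, guarding against edge-staining artifacts.
    min_roi_area_um2:
        Minimum ROI area for a spot to be analyzed (strictly exceeded);
        ~5% of the ROI of an intact 1-mm spot.
    tissue_od_floor:
        Total optical density above which a pixel counts as tissue.
    min_speck_px:
        Connected tissue components smaller than this are treated as dust.
    hema_od_vector / dab_od_vector:
        Stain unit vectors in OD space for the color deconvolution.
    ridge_scale_um:
        Width (µm) of the curvilinear structures the ridge filter targets.
    min_dab_od:
        DAB optical-density floor a membrane pixel must reach.
    gap_px:
        Maximum end-to-end gap (pixels) bridged when merging imperfectly
        connected membrane fragments.
    min_fragment_px:
        Skeleton fragments smaller than this are eliminated.
    c_low / c_high:
        Fragment-size cut-offs (skeleton pixels) between which the
        per-fragment connectivity weight ramps from 0 to 1.
    score_t_low / score_t_high:
        Connectivity cut-points mapping to the ordinal HER2 score
        (<= t_low -> 0/1+, <= t_high -> 2+, else 3+).
    kappa_weights:
        Disagreement weighting for the kappa statistic ("linear").
    aggregation:
        Per-patient summary of spot scores ("max", "mode" or "median").
    min_spots:
        Minimum number of adequate spots for a patient-level summary.
    seed:
        Seed for any stochastic step (synthetic data only; the analysis
        itself is deterministic).
    """

    mpp: float = 0.25
    margin_px: int = 100
    min_roi_area_um2: float = 37_000.0
    tissue_od_floor: float = 0.1
    min_speck_px: int = 100
    hema_od_vector: tuple[float, float, float] = DEFAULT_HEMATOXYLIN_OD
    dab_od_vector: tuple[float, float, float] = DEFAULT_DAB_OD
    ridge_scale_um: float = 1.0
    min_dab_od: float = 0.15
    gap_px: int = 3
    min_fragment_px: int = 10
    c_low: int = 50
    c_high: int = 500
    score_t_low: float = 0.12
    score_t_high: float = 0.56
    kappa_weights: str = "linear"
    aggregation: str = "max"
    min_spots: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ConfigError(f"mpp must be positive, got {self.mpp}")
        if self.margin_px < 0:
            raise ConfigError("margin_px must be non-negative")
        if self.min_roi_area_um2 < 0:
            raise ConfigError("min_roi_area_um2 must be non-negative")
        if not 0 < self.score_t_low < self.score_t_high <= 1:
            raise ConfigError(
                "score thresholds must satisfy 0 < t_low < t_high <= 1, got "
                f"t_low={self.score_t_low}, t_high={self.score_t_high}"
            )
        if not 0 < self.c_low < self.c_high:
            raise ConfigError(
                f"fragment cut-offs must satisfy 0 < c_low < c_high, got "
                f"c_low={self.c_low}, c_high={self.c_high}"
            )
        if self.gap_px < 0 or self.min_fragment_px < 0:
            raise ConfigError("gap_px and min_fragment_px must be non-negative")
        if self.ridge_scale_um <= 0:
            raise ConfigError("ridge_scale_um must be positive")
        if self.kappa_weights not in ("linear", "quadratic"):
            raise ConfigError(f"unknown kappa weighting {self.kappa_weights!r}")
        if self.aggregation not in ("max", "mode", "median"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        if self.min_spots < 1:
            raise ConfigError("min_spots must be >= 1")
        self.hema_od_vector = tuple(float(v) for v in self.hema_od_vector)
        self.dab_od_vector = tuple(float(v) for v in self.dab_od_vector)
        if len(self.hema_od_vector) != 3 or len(self.dab_od_vector) != 3:
            raise ConfigError("stain vectors must have three components")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | None = None) -> RunConfig:
    """Load a :class:`RunConfig` from a JSON file, or the defaults.

    An empty file or ``None`` yields the full default configuration;
    unknown keys are rejected.
    """
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read().strip()
    if not text:
        return RunConfig()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config JSON must be an object")
    return RunConfig.from_dict(data)


def run_log(config: RunConfig, inputs: dict[str, Any] | None = None) -> dict[str, Any]:
    """Structured log header recording the full effective configuration.

    The analysis parameters are deliberately not tuned per dataset, so
    every run records exactly which values were in effect.
    """
    import numpy
    import skimage

    from . import __version__

    return {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "memconnect": __version__,
        "python": platform.python_version(),
        "numpy": numpy.__version__,
        "skimage": skimage.__version__,
        "config": config.to_dict(),
        "inputs": dict(inputs or {}),
    }
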