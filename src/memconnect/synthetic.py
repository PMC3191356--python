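"""Synthetic IHC spot images and score/FISH cohorts with ground truth.

No public image set accompanies the membrane-connectivity method, so this
module renders hematoxylin+DAB tissue spots whose membrane staining is
controllable: cells are packed as touching discs on a circular tissue
spot, and for each cell a contiguous arc covering ``membrane_completeness``
of its perimeter is rendered as DAB membrane through the forward
Beer-Lambert model, over a hematoxylin counterstain with nuclei and
Gaussian optical-density noise.  Contiguous arcs are the worst case for
connectivity at a fixed stained fraction, so the completeness-to-
connectivity mapping is generator-specific and monotone by construction.

The cohort simulator emulates the structure of a TMA concordance study:
a latent HER2 category per patient, 1-4 spots per patient, two visual
raters whose discordance is concentrated in the 2+ category with no
two-category flips, a per-spot connectivity drawn within the digital
score's band (bimodal overall), and per-patient FISH counts that are
lognormal with a controllable log-scale correlation against the patient's
maximum connectivity.

Everything is reproducible bit-for-bit from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd

from .config import InputError
from .connectivity import SCORE_LABELS
from .stains import SpotImage, od_to_rgb


# ---------------------------------------------------------------------------
# spot images


@dataclass
class SpotSimParams:
    """Parameters of the synthetic spot-image generator.

    Defaults emulate a 1-mm TMA core scanned at 0.25 µm/px, densely packed
    with ~8-µm-radius tumour cells; ``membrane_completeness`` is the
    fraction of each cell perimeter carrying DAB membrane staining and
    ``dab_intensity`` its optical density.
    """

    n_cells: int = 1200
    cell_radius_um: float = 8.0
    scatter_fraction: float = 0.1
    membrane_completeness: float = 1.0
    completeness_concentration: float = 10.0
    dab_intensity: float = 0.8
    background_noise_sd: float = 0.05
    mpp: float = 0.25
    spot_diameter_um: float = 1000.0
    membrane_thickness_um: float = 1.0
    hema_base_od: float = 0.25
    nucleus_od: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.membrane_completeness <= 1.0:
            raise InputError("membrane_completeness must lie in [0, 1]")
        if not 0.0 <= self.scatter_fraction <= 1.0:
            raise InputError("scatter_fraction must lie in [0, 1]")
        for name in (
            "n_cells",
            "cell_radius_um",
            "dab_intensity",
            "mpp",
            "spot_diameter_um",
            "membrane_thickness_um",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.background_noise_sd < 0:
            raise InputError("background_noise_sd must be non-negative")


def _hex_lattice(radius_px: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points (row, col offsets) within a disc."""
    rows = []
    dy = spacing * np.sqrt(3.0) / 2.0
    n = int(radius_px / dy) + 2
    for i in range(-n, n + 1):
        y = i * dy
        x_off = 0.0 if i % 2 == 0 else spacing / 2.0
        m = int(radius_px / spacing) + 2
        for j in range(-m, m + 1):
            x = j * spacing + x_off
            if x * x + y * y <= radius_px * radius_px:
                rows.append((y, x))
    return np.asarray(rows, dtype=float)


def _islet_sizes(n: int) -> list[int]:
    """Split n scattered cells into islets of 3 (and 2) touching cells."""
    if n == 1:
        return [1]
    sizes = [3] * (n // 3)
    rem = n % 3
    if rem == 2:
        sizes.append(2)
    elif rem == 1:
        sizes[-1] = 2
        sizes.append(2)
    return sizes


def generate_spot_image(params: SpotSimParams) -> tuple[SpotImage, dict[str, Any]]:
    """Render one synthetic spot; returns the image and its ground truth.

    The ground truth carries the pre-noise membrane pixel mask, the tissue
    disc mask, cell centres (pixels) and the per-cell completeness.

    Raises
    ------
    InputError
        When ``n_cells`` circles of the requested radius cannot be packed
        on the spot without overlap.
    """
    rng = np.random.default_rng(params.seed)
    r_px = params.cell_radius_um / params.mpp
    disc_r = params.spot_diameter_um / (2.0 * params.mpp)
    pad = 10
    size = int(np.ceil(2 * disc_r)) + 2 * pad
    center = size / 2.0

    spacing = 2.0 * r_px + 1.0
    sites = _hex_lattice(disc_r - r_px - 2.0, spacing)
    if len(sites) < params.n_cells:
        raise InputError(
            f"infeasible packing: only {len(sites)} sites for {params.n_cells} cells; "
            "reduce n_cells or cell_radius_um, or enlarge the spot"
        )
    # most cells form a compact nest of touching cells around a jittered
    # centre; the remainder sit in small detached islets of 2-3 touching
    # cells away from the nest, as in tissue with detached tumour nests
    n_scatter = int(round(params.scatter_fraction * params.n_cells))
    n_nest = params.n_cells - n_scatter
    anchor = rng.uniform(-0.1 * disc_r, 0.1 * disc_r, size=2)
    order = np.argsort(((sites - anchor) ** 2).sum(axis=1))
    nest = sites[order[:n_nest]]
    scattered: list[np.ndarray] = []
    if n_scatter:
        group_sizes = _islet_sizes(n_scatter)
        nest_reach = np.sqrt(((nest - anchor) ** 2).sum(axis=1)).max() if n_nest else 0.0
        # islets stay well inside the spot so an ROI edge margin does not
        # clip them, and clear of the nest and of each other
        dy = spacing * np.sqrt(3.0) / 2.0
        neighbour_offsets = np.array([(0.0, spacing), (dy, spacing / 2.0)])
        radius_cap = 0.8 * disc_r - 1.5 * spacing
        candidates = sites[order[n_nest:]]
        dist = np.sqrt(((candidates - anchor) ** 2).sum(axis=1))
        far = candidates[(dist > nest_reach + 1.5 * spacing) & (dist < radius_cap)]
        rng.shuffle(far)
        anchors: list[np.ndarray] = []
        for site in far:
            if len(anchors) == len(group_sizes):
                break
            if all(((site - a) ** 2).sum() >= (3 * spacing) ** 2 for a in anchors):
                anchors.append(site)
        if len(anchors) < len(group_sizes):
            raise InputError(
                "infeasible packing: not enough room for detached islets; "
                "reduce n_cells or scatter_fraction, or enlarge the spot"
            )
        for anchor_site, group in zip(anchors, group_sizes):
            scattered.append(anchor_site)
            for k in range(group - 1):
                scattered.append(anchor_site + neighbour_offsets[k])
    centers = (
        np.vstack([nest] + ([np.asarray(scattered)] if scattered else []))
        if n_nest
        else np.asarray(scattered)
    ) + center

    yy, xx = np.ogrid[:size, :size]
    disc_mask = (yy - center) ** 2 + (xx - center) ** 2 <= disc_r**2

    membrane = np.zeros((size, size), dtype=bool)
    nuclei = np.zeros((size, size), dtype=bool)
    thickness_px = max(1.0, params.membrane_thickness_um / params.mpp)
    radii = np.arange(r_px - thickness_px / 2.0, r_px + thickness_px / 2.0 + 0.25, 0.5)
    n_theta = max(8, int(4.0 * 2.0 * np.pi * r_px))
    start_angles = rng.uniform(0.0, 2.0 * np.pi, size=params.n_cells)
    # per-cell completeness: staining is heterogeneous across cells, so each
    # cell draws its stained fraction from a Beta around the requested mean
    # (degenerate at the endpoints 0 and 1)
    mean_c = params.membrane_completeness
    if mean_c in (0.0, 1.0):
        cell_completeness = np.full(params.n_cells, mean_c)
    else:
        kappa = params.completeness_concentration
        cell_completeness = rng.beta(
            mean_c * kappa, (1.0 - mean_c) * kappa, size=params.n_cells
        )
    nucleus_r = 0.45 * r_px
    for (cy, cx), theta0, comp in zip(centers, start_angles, cell_completeness):
        span = comp * 2.0 * np.pi
        if span > 0:
            m = max(2, int(n_theta * comp))
            theta = theta0 + np.linspace(0.0, span, m)
            for rad in radii:
                ys = np.round(cy + rad * np.sin(theta)).astype(int)
                xs = np.round(cx + rad * np.cos(theta)).astype(int)
                membrane[ys, xs] = True
        ny, nx = np.ogrid[
            int(cy - nucleus_r) : int(cy + nucleus_r) + 1,
            int(cx - nucleus_r) : int(cx + nucleus_r) + 1,
        ]
        nuclei[ny, nx] = nuclei[ny, nx] | (
            (ny - cy) ** 2 + (nx - cx) ** 2 <= nucleus_r**2
        )

    dab_od = np.where(membrane, params.dab_intensity, 0.0)
    hema_od = np.where(disc_mask, params.hema_base_od, 0.0)
    hema_od = hema_od + np.where(nuclei, params.nucleus_od, 0.0)
    if params.background_noise_sd > 0:
        noise = rng.normal(0.0, params.background_noise_sd, size=(size, size, 2))
        dab_od = dab_od + np.where(disc_mask, noise[..., 0], 0.0)
        hema_od = hema_od + np.where(disc_mask, noise[..., 1], 0.0)
    dab_od = np.clip(dab_od, 0.0, None)
    hema_od = np.clip(hema_od, 0.0, None)

    pixels = od_to_rgb(hema_od, dab_od, quantize=True)
    image = SpotImage(pixels=pixels, mpp=params.mpp, spot_id=f"synthetic-{params.seed}")
    truth = {
        "membrane": membrane,
        "tissue": disc_mask,
        "cell_centers": centers,
        "cell_radius_px": r_px,
        "completeness": cell_completeness,
    }
    return image, truth


# ---------------------------------------------------------------------------
# cohorts

#: default rater confusion, conditional on the latent spot category
#: (rows = latent category, columns = observed category).  Off-diagonal
#: mass sits next to the diagonal only — raters never flip two categories —
#: and is concentrated around the equivocal 2+ category, mirroring the
#: discordance pattern of published TMA concordance data at the same
#: operating point.
DEFAULT_VE2_CONFUSION = (
    (475 / 490, 15 / 490, 0.0),
    (0.0, 21 / 25, 4 / 25),
    (0.0, 4 / 60, 56 / 60),
)
DEFAULT_DA_CONFUSION = (
    (458 / 490, 32 / 490, 0.0),
    (4 / 25, 18 / 25, 3 / 25),
    (0.0, 0.0, 1.0),
)
IDENTITY_CONFUSION = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))

#: connectivity bands of the three categories (boundaries belong below)
_SCORE_BANDS = ((0.0, 0.12), (0.12, 0.56), (0.56, 1.0))
#: beta shapes of the within-band connectivity draw, giving the bimodal,
#: left-asymmetric distribution seen in real cohorts
_BAND_SHAPES = ((1.0, 4.0), (2.0, 2.0), (3.0, 1.5))


@dataclass
class CohortSimParams:
    """Parameters of the synthetic score/FISH cohort generator.

    Defaults reproduce the operating point of a 177-patient TMA cohort
    with 575 spots: 1-4 spots per patient, ~85% latent-negative patients,
    rater discordance concentrated in the 2+ category, and FISH counts
    lognormal with a log-scale correlation of 0.67 between mean HER2 per
    cell and the patient's maximum connectivity.
    """

    n_patients: int = 177
    spots_per_patient_probs: tuple[float, ...] = (16 / 177, 15 / 177, 55 / 177, 91 / 177)
    score_probs: tuple[float, float, float] = (490 / 575, 25 / 575, 60 / 575)
    ve2_confusion: tuple = DEFAULT_VE2_CONFUSION
    da_confusion: tuple = DEFAULT_DA_CONFUSION
    fix_composition: bool = True
    rho_her2: float = 0.67
    rho_cep17: float = 0.39
    log_her2_mean: float = float(np.log(4.5))
    log_her2_sd: float = 0.75
    log_cep17_mean: float = float(np.log(2.5))
    log_cep17_sd: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InputError("n_patients must be >= 1")
        for name in ("spots_per_patient_probs", "score_probs"):
            probs = np.asarray(getattr(self, name), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise InputError(f"{name} must be a probability vector")
        for name in ("rho_her2", "rho_cep17"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise InputError(f"{name} must lie in [-1, 1]")
        for mat in (self.ve2_confusion, self.da_confusion):
            arr = np.asarray(mat, dtype=float)
            if arr.shape != (3, 3) or (arr < 0).any() or not np.allclose(
                arr.sum(axis=1), 1.0
            ):
                raise InputError("confusion matrices must be 3x3 row-stochastic")


def _largest_remainder(n: int, probs: np.ndarray) -> np.ndarray:
    """Integer counts summing to n, proportional to probs."""
    raw = n * np.asarray(probs, dtype=float)
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _sample_connectivity(rng: np.random.Generator, category: int) -> float:
    lo, hi = _SCORE_BANDS[category]
    a, b = _BAND_SHAPES[category]
    u = rng.beta(a, b)
    # strictly inside the half-open band so the category maps back exactly
    return float(np.nextafter(lo, hi) + u * (hi - np.nextafter(lo, hi)))


def generate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a spot-score table and a per-patient FISH table.

    Returns ``(spots, fish)``: spots has one row per TMA spot with columns
    patient_id, spot_id, ve1, ve2, da (category labels), connectivity and
    adequate; fish has one row per patient with columns patient_id,
    her2_mean, cep17_mean and ratio.
    """
    rng = np.random.default_rng(params.seed)
    n_spot_choices = np.arange(1, len(params.spots_per_patient_probs) + 1)
    ve2_conf = np.asarray(params.ve2_confusion, dtype=float)
    da_conf = np.asarray(params.da_confusion, dtype=float)

    if params.fix_composition:
        # reproduce the cohort composition exactly (the operating point is
        # one fixed cohort); only the assignment to patients is random
        truth_counts = _largest_remainder(params.n_patients, params.score_probs)
        truths = rng.permutation(np.repeat(np.arange(3), truth_counts))
        spot_counts = _largest_remainder(
            params.n_patients, params.spots_per_patient_probs
        )
        spots_per_patient = rng.permutation(np.repeat(n_spot_choices, spot_counts))
    else:
        truths = rng.choice(3, size=params.n_patients, p=params.score_probs)
        spots_per_patient = rng.choice(
            n_spot_choices, size=params.n_patients, p=params.spots_per_patient_probs
        )

    spot_rows = []
    connect_max = np.zeros(params.n_patients)
    for p in range(params.n_patients):
        pid = f"P{p + 1:04d}"
        truth = int(truths[p])
        n_spots = int(spots_per_patient[p])
        cmax = 0.0
        for s in range(n_spots):
            ve1 = truth
            ve2 = int(rng.choice(3, p=ve2_conf[ve1]))
            da = int(rng.choice(3, p=da_conf[ve1]))
            conn = _sample_connectivity(rng, da)
            cmax = max(cmax, conn)
            spot_rows.append(
                {
                    "patient_id": pid,
                    "spot_id": f"{pid}-S{s + 1}",
                    "ve1": SCORE_LABELS[ve1],
                    "ve2": SCORE_LABELS[ve2],
                    "da": SCORE_LABELS[da],
                    "connectivity": round(conn, 6),
                    "adequate": True,
                }
            )
        connect_max[p] = cmax

    log_cmax = np.log(connect_max)
    sd = log_cmax.std()
    z = (log_cmax - log_cmax.mean()) / sd if sd > 0 else np.zeros_like(log_cmax)
    eps_h = rng.standard_normal(params.n_patients)
    eps_c = rng.standard_normal(params.n_patients)
    log_her2 = params.log_her2_mean + params.log_her2_sd * (
        params.rho_her2 * z + np.sqrt(1.0 - params.rho_her2**2) * eps_h
    )
    log_cep17 = params.log_cep17_mean + params.log_cep17_sd * (
        params.rho_cep17 * z + np.sqrt(1.0 - params.rho_cep17**2) * eps_c
    )
    her2 = np.exp(log_her2)
    cep17 = np.exp(log_cep17)
    fish = pd.DataFrame(
        {
            "patient_id": [f"P{p + 1:04d}" for p in range(params.n_patients)],
            "her2_mean": np.round(her2, 3),
            "cep17_mean": np.round(cep17, 3),
            "ratio": np.round(her2 / cep17, 3),
        }
    )
    return pd.DataFrame(spot_rows), fish
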