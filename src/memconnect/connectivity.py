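"""Skeleton fragments and the membrane-connectivity statistic.

The binary membrane mask is thinned to a one-pixel-wide skeleton, broken
into 8-connected fragments, post-processed (imperfectly connected
membranes merged across small gaps, tiny fragments eliminated), and
summarized by *connectivity*: a statistic in [0, 1] computed from the
fragment-size distribution.  The size of a fragment is the number of
pixels its skeleton is composed of.  Connectivity is 0 when no fragment
exceeds a low size cut-off, 1 when every fragment exceeds a high cut-off,
and interpolates continuously in between via the size-weighted ramp

    C = sum_i a_i * w(a_i) / sum_i a_i,
    w(a) = clip((a - c_low) / (c_high - c_low), 0, 1).

The continuous estimate maps onto the ordinal HER2 score with fixed
cut-points: 0/1+ for C <= 0.12, 2+ for 0.12 < C <= 0.56, 3+ above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology

from .config import InputError
from .stains import MembraneMask

#: ordinal HER2 categories in rank order (0 and 1+ merged as negative)
SCORE_LABELS = ("0/1+", "2+", "3+")


@dataclass
class ConnectivityParams:
    """Fragment-size cut-offs and post-processing parameters.

    ``c_low``/``c_high`` are in skeleton pixels; ``gap_px`` is the largest
    end-to-end gap bridged when merging fragments; fragments smaller than
    ``min_fragment_px`` are eliminated before scoring.
    """

    c_low: int = 50
    c_high: int = 500
    gap_px: int = 3
    min_fragment_px: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.c_low < self.c_high:
            raise InputError(
                f"cut-offs must satisfy 0 < c_low < c_high, got {self.c_low}, {self.c_high}"
            )
        if self.gap_px < 0 or self.min_fragment_px < 0:
            raise InputError("gap_px and min_fragment_px must be non-negative")


@dataclass
class FragmentSet:
    """Labelled membrane skeleton with per-fragment pixel counts.

    ``labels`` is an H×W integer array (0 = background, k > 0 = fragment id
    on skeleton pixels); ``sizes[k-1]`` is the pixel count of fragment k.
    """

    labels: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.sizes = np.asarray(self.sizes, dtype=int)

    @property
    def n_fragments(self) -> int:
        return int(self.sizes.size)

    @property
    def total_px(self) -> int:
        return int(self.sizes.sum())

    @property
    def skeleton(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ConnectivityResult:
    """Connectivity in [0, 1] plus its categorical HER2 score."""

    connectivity: float
    her2_score: str
    n_fragments: int
    total_skeleton_px: int


def _label_skeleton(skel: np.ndarray) -> FragmentSet:
    labels = measure.label(skel, connectivity=2)
    sizes = np.bincount(labels.ravel())[1:]
    return FragmentSet(labels=labels, sizes=sizes)


def skeletonize_mask(mask: MembraneMask | np.ndarray) -> FragmentSet:
    """Thin a membrane mask to a 1-px skeleton and label its fragments."""
    arr = mask.mask if isinstance(mask, MembraneMask) else np.asarray(mask, bool)
    if not arr.any():
        return FragmentSet(labels=np.zeros(arr.shape, dtype=int), sizes=np.zeros(0))
    return _label_skeleton(morphology.skeletonize(arr))


def link_fragments(frags: FragmentSet, gap_px: int = 3) -> FragmentSet:
    """Merge skeleton fragments separated by gaps of at most ``gap_px``.

    Implemented as dilation of the skeleton by ``ceil(gap_px / 2)``
    followed by re-skeletonization, so endpoints within ``gap_px`` of each
    other reconnect.  ``gap_px = 0`` is the identity.
    """
    if gap_px < 0:
        raise InputError("gap_px must be non-negative")
    if gap_px == 0 or frags.n_fragments == 0:
        return frags
    radius = math.ceil(gap_px / 2)
    dilated = morphology.dilation(frags.skeleton, morphology.disk(radius))
    return _label_skeleton(morphology.skeletonize(dilated))


def prune_fragments(frags: FragmentSet, min_fragment_px: int = 10) -> FragmentSet:
    """Eliminate fragments with fewer than ``min_fragment_px`` pixels."""
    if min_fragment_px < 0:
        raise InputError("min_fragment_px must be non-negative")
    if frags.n_fragments == 0 or min_fragment_px == 0:
        return frags
    keep = frags.sizes >= min_fragment_px
    if keep.all():
        return frags
    old_ids = np.flatnonzero(keep) + 1
    remap = np.zeros(frags.n_fragments + 1, dtype=int)
    remap[old_ids] = np.arange(1, old_ids.size + 1)
    return FragmentSet(labels=remap[frags.labels], sizes=frags.sizes[keep])


def connectivity(sizes: np.ndarray, params: ConnectivityParams) -> float:
    """Size-weighted ramp connectivity of a fragment-size distribution.

    Returns 0 for an empty fragment set, 0 when every fragment is at or
    below ``c_low``, 1 when every fragment is at or above ``c_high``, and
    the size-weighted mean of the ramp weight in between.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        return 0.0
    if (sizes <= 0).any():
        raise InputError("fragment sizes must be positive")
    weights = np.clip((sizes - params.c_low) / (params.c_high - params.c_low), 0.0, 1.0)
    return float(np.sum(sizes * weights) / np.sum(sizes))


def score_from_connectivity(
    c: float,
    t_low: float = 0.12,
    t_high: float = 0.56,
) -> str:
    """Ordinal HER2 score of a connectivity value.

    Boundaries belong to the lower category: 0/1+ for ``c <= t_low``,
    2+ for ``t_low < c <= t_high``, 3+ for ``t_high < c <= 1``.
    """
    if not 0.0 <= c <= 1.0:
        raise InputError(f"connectivity must lie in [0, 1], got {c}")
    if c <= t_low:
        return SCORE_LABELS[0]
    if c <= t_high:
        return SCORE_LABELS[1]
    return SCORE_LABELS[2]


def compute_connectivity(
    mask: MembraneMask | np.ndarray,
    params: ConnectivityParams | None = None,
    t_low: float = 0.12,
    t_high: float = 0.56,
) -> ConnectivityResult:
    """Full post-processing chain: skeletonize, link, prune, score."""
    params = params or ConnectivityParams()
    frags = skeletonize_mask(mask)
    frags = link_fragments(frags, params.gap_px)
    frags = prune_fragments(frags, params.min_fragment_px)
    c = connectivity(frags.sizes, params)
    return ConnectivityResult(
        connectivity=c,
        her2_score=score_from_connectivity(c, t_low, t_high),
        n_fragments=frags.n_fragments,
        total_skeleton_px=frags.total_px,
    )
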