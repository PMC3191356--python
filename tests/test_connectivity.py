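"""Skeleton post-processing and the connectivity statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage import draw

from memconnect import (
    ConnectivityParams,
    InputError,
    compute_connectivity,
    connectivity,
    link_fragments,
    prune_fragments,
    score_from_connectivity,
    skeletonize_mask,
)

PARAMS = ConnectivityParams(c_low=50, c_high=550)


def solid_ring(center, outer=20, inner=15, shape=(100, 100)):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw.disk(center, outer, shape=shape)
    mask[rr, cc] = True
    rr, cc = draw.disk(center, inner, shape=shape)
    mask[rr, cc] = False
    return mask


def two_segments(gap: int, length: int = 30):
    mask = np.zeros((21, 2 * length + gap + 20), dtype=bool)
    mask[10, 10 : 10 + length] = True
    mask[10, 10 + length + gap : 10 + 2 * length + gap] = True
    return mask


class TestSkeletonize:
    def test_empty_mask_yields_no_fragments(self):
        frags = skeletonize_mask(np.zeros((30, 30), dtype=bool))
        assert frags.n_fragments == 0
        assert frags.total_px == 0

    def test_solid_ring_thins_to_one_closed_loop(self):
        frags = skeletonize_mask(solid_ring((50, 50)))
        assert frags.n_fragments == 1
        skel = frags.skeleton
        neighbours = ndi.convolve(skel.astype(int), np.ones((3, 3)), mode="constant") - 1
        assert np.all(neighbours[skel] == 2)  # closed 1-px loop

    def test_disjoint_rings_stay_disjoint(self):
        mask = solid_ring((40, 40), shape=(160, 160)) | solid_ring((110, 110), shape=(160, 160))
        assert skeletonize_mask(mask).n_fragments == 2


class TestLinking:
    def test_small_gap_is_bridged(self):
        frags = skeletonize_mask(two_segments(gap=3))
        assert frags.n_fragments == 2
        linked = link_fragments(frags, gap_px=5)
        assert linked.n_fragments == 1

    def test_gap_beyond_reach_is_not_bridged(self):
        frags = skeletonize_mask(two_segments(gap=3))
        linked = link_fragments(frags, gap_px=2)
        assert linked.n_fragments == 2

    def test_zero_gap_is_identity(self):
        mask = solid_ring((50, 50), shape=(150, 150))
        mask[100:121, 40:123] = two_segments(gap=3)
        frags = skeletonize_mask(mask)
        linked = link_fragments(frags, gap_px=0)
        assert linked.n_fragments == frags.n_fragments
        assert sorted(linked.sizes) == sorted(frags.sizes)


class TestPruning:
    def test_fragments_below_threshold_removed(self):
        mask = two_segments(gap=10, length=40)
        mask[5, 0:3] = True  # 3-px speck
        frags = skeletonize_mask(mask)
        pruned = prune_fragments(frags, min_fragment_px=10)
        assert pruned.n_fragments == 2
        assert all(size >= 10 for size in pruned.sizes)
        assert set(np.unique(pruned.labels)) == {0, 1, 2}

    def test_zero_threshold_is_identity(self):
        frags = skeletonize_mask(two_segments(gap=10))
        pruned = prune_fragments(frags, min_fragment_px=0)
        assert pruned is frags

    def test_all_fragments_pruned_gives_zero_connectivity(self):
        frags = skeletonize_mask(two_segments(gap=10, length=5))
        pruned = prune_fragments(frags, min_fragment_px=100)
        assert pruned.n_fragments == 0
        assert connectivity(pruned.sizes, PARAMS) == 0.0


class TestConnectivityStatistic:
    def test_no_fragment_above_low_cutoff_gives_zero(self):
        assert connectivity(np.array([5, 20, 50]), PARAMS) == 0.0

    def test_all_fragments_above_high_cutoff_give_one(self):
        assert connectivity(np.array([550, 600, 10_000]), PARAMS) == 1.0

    def test_hand_evaluated_example(self):
        # (100*0.1 + 600*1) / 700
        c = connectivity(np.array([100, 600]), PARAMS)
        assert c == pytest.approx(61.0 / 70.0, abs=1e-12)

    def test_empty_size_list_gives_zero(self):
        assert connectivity(np.array([]), PARAMS) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 1000), min_size=0, max_size=20),
        cuts=st.tuples(st.integers(1, 400), st.integers(401, 900)),
    )
    def test_matches_brute_force_evaluation(self, sizes, cuts):
        params = ConnectivityParams(c_low=cuts[0], c_high=cuts[1])
        expected = 0.0
        if sizes:
            num = den = 0.0
            for a in sizes:
                w = min(max((a - cuts[0]) / (cuts[1] - cuts[0]), 0.0), 1.0)
                num += a * w
                den += a
            expected = num / den
        assert connectivity(np.array(sizes), params) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 1000), min_size=1, max_size=15),
        factor=st.integers(2, 7),
    )
    def test_scale_covariance(self, sizes, factor):
        """Scaling all sizes and both cut-offs leaves connectivity unchanged."""
        sizes = np.array(sizes)
        base = connectivity(sizes, PARAMS)
        scaled = connectivity(
            sizes * factor,
            ConnectivityParams(c_low=PARAMS.c_low * factor, c_high=PARAMS.c_high * factor),
        )
        assert scaled == pytest.approx(base, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 1000), min_size=2, max_size=15),
        data=st.data(),
    )
    def test_merging_fragments_never_decreases_connectivity(self, sizes, data):
        i = data.draw(st.integers(0, len(sizes) - 1))
        j = data.draw(st.integers(0, len(sizes) - 1).filter(lambda x: x != i))
        merged = [s for k, s in enumerate(sizes) if k not in (i, j)]
        merged.append(sizes[i] + sizes[j])
        assert connectivity(np.array(merged), PARAMS) >= connectivity(
            np.array(sizes), PARAMS
        ) - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(sizes=st.lists(st.integers(1, 1000), min_size=1, max_size=15))
    def test_pruning_sublow_fragments_never_decreases_connectivity(self, sizes):
        sizes = np.array(sizes)
        kept = sizes[sizes >= PARAMS.c_low]
        pruned_c = connectivity(kept, PARAMS) if kept.size else 0.0
        assert pruned_c >= connectivity(sizes, PARAMS) - 1e-12

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(InputError):
            connectivity(np.array([10, 0]), PARAMS)


class TestScoreMapping:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.0, "0/1+"),
            (0.12, "0/1+"),   # boundary belongs to the lower category
            (0.121, "2+"),
            (0.56, "2+"),
            (0.561, "3+"),
            (1.0, "3+"),
        ],
    )
    def test_cut_point_handling(self, value, expected):
        assert score_from_connectivity(value) == expected

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(InputError):
                score_from_connectivity(bad)

    def test_monotone_in_connectivity(self):
        grid = np.linspace(0, 1, 101)
        codes = [("0/1+", "2+", "3+").index(score_from_connectivity(c)) for c in grid]
        assert all(b >= a for a, b in zip(codes, codes[1:]))


def test_full_chain_on_ring_mask():
    """Skeletonize→link→prune→score on a clean ring gives a single loop."""
    result = compute_connectivity(solid_ring((50, 50)), PARAMS)
    assert result.n_fragments == 1
    assert 0.0 <= result.connectivity <= 1.0
    assert result.her2_score == score_from_connectivity(result.connectivity)
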