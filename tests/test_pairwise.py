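"""Pairwise alignment: naive anchoring, segmentation, and the modified DP
checked against exhaustive enumeration of monotone matchings."""

from functools import lru_cache

import numpy as np
import pytest

from pcans.pairwise import (
    align_pair,
    dp_align_segment,
    naive_align,
    pairing_total_score,
    segment_unaligned,
)
from pcans.similarity import score
from pcans.types import AlignmentParams, PeakProfile

from conftest import make_profile


def brute_force_best(S_peaks, T_peaks, params):
    """Independent oracle: best total score over all crossover-free
    matchings, scoring gp per unmatched peak and excluding pairings that
    violate the movement window or the similarity floor."""

    def pair_value(i, j):
        if abs(S_peaks[i].position - T_peaks[j].position) > params.m:
            return None
        s = score(S_peaks[i], T_peaks[j], params)
        return s if s >= params.min_score else None

    @lru_cache(maxsize=None)
    def best(i, j):
        if i == len(S_peaks):
            return (len(T_peaks) - j) * params.gp
        if j == len(T_peaks):
            return (len(S_peaks) - i) * params.gp
        options = [best(i + 1, j) + params.gp, best(i, j + 1) + params.gp]
        v = pair_value(i, j)
        if v is not None:
            options.append(best(i + 1, j + 1) + v)
        return max(options)

    return best(0, 0)


def random_segment(rng, n, spread=0.08):
    center = 3.0
    positions = np.sort(center + rng.uniform(-spread, spread, n))
    heights = rng.lognormal(np.log(5.0), 0.6, n)
    widths = np.clip(rng.normal(0.004, 0.001, n), 0.001, None)
    return make_profile(f"seg{rng.integers(1 << 30)}", positions, heights, widths).peaks


class TestNaive:
    def test_identical_profiles_fully_anchored(self, params):
        P = make_profile("A", [2.1, 2.5, 3.0])
        Q = make_profile("B", [2.1, 2.5, 3.0])
        anchors = naive_align(P, Q, params)
        assert [(a.left, a.right) for a in anchors] == [(0, 0), (1, 1), (2, 2)]
        assert all(a.stage == "naive" for a in anchors)
        assert segment_unaligned(P, Q, anchors, params) == []

    def test_half_height_difference_not_anchored(self, params):
        P = make_profile("A", [2.1, 2.5, 3.0], heights=[10, 10, 10])
        Q = make_profile("B", [2.1, 2.5, 3.0], heights=[10, 15, 10])
        anchors = naive_align(P, Q, params)  # height term 10/15 < 0.90
        assert [(a.left, a.right) for a in anchors] == [(0, 0), (2, 2)]

    def test_empty_profile_gives_no_anchors(self, params):
        P = make_profile("A", [2.1])
        Q = PeakProfile("B", [])
        assert naive_align(P, Q, params) == []

    def test_anchors_are_crossover_free(self, params, rng):
        for _ in range(50):
            P = make_profile("A", np.sort(rng.uniform(2, 4, 10)))
            Q = make_profile("B", np.sort(rng.uniform(2, 4, 10)))
            anchors = naive_align(P, Q, params)
            rights = [a.right for a in anchors]
            assert rights == sorted(rights)


class TestSegmentation:
    def test_single_connected_cluster_is_one_segment(self, params):
        P = make_profile("A", [3.00, 3.02], heights=[10, 20])
        Q = make_profile("B", [3.01, 3.03], heights=[20, 10])
        segs = segment_unaligned(P, Q, [], params)
        assert len(segs) == 1
        assert segs[0].left_range == (0, 2) and segs[0].right_range == (0, 2)

    def test_clusters_beyond_window_split(self, params):
        P = make_profile("A", [3.00, 3.50], heights=[10, 20])
        Q = make_profile("B", [3.01, 3.51], heights=[20, 10])
        segs = segment_unaligned(P, Q, [], params)
        assert len(segs) == 2

    def test_isolated_peak_forms_empty_sided_segment(self, params):
        P = make_profile("A", [3.00, 3.20], heights=[10, 10])
        Q = make_profile("B", [3.01], heights=[20])
        segs = segment_unaligned(P, Q, [], params)
        sides = sorted((s.left_range, s.right_range) for s in segs)
        assert ((0, 1), (0, 1)) in sides  # 3.00 vs 3.01 connected
        assert any(lr == (1, 2) and rr[0] == rr[1] for lr, rr in sides)


class TestDP:
    def test_single_compatible_pair_aligns(self, params):
        S = make_profile("A", [3.00]).peaks
        T = make_profile("B", [3.02]).peaks
        out = dp_align_segment(S, T, params)
        assert [(p.left, p.right) for p in out if not p.is_gap] == [(0, 0)]

    def test_pair_beyond_window_gaps_both(self, params):
        S = make_profile("A", [3.00]).peaks
        T = make_profile("B", [3.10]).peaks
        out = dp_align_segment(S, T, params)
        assert all(p.is_gap for p in out) and len(out) == 2

    def test_empty_side_gaps_everything(self, params):
        S = make_profile("A", [3.0, 3.1, 3.2]).peaks
        out = dp_align_segment(S, [], params)
        assert len(out) == 3 and all(p.is_gap for p in out)

    def test_one_good_pair_beats_two_mediocre(self):
        # heights chosen so the cross pairs score ~0.62 and the matched
        # middle pair scores ~0.95; gp = -0.10
        params = AlignmentParams()
        S = make_profile("A", [3.000], heights=[10.0]).peaks
        T = make_profile("B", [2.999, 3.020], heights=[10.2, 1.0]).peaks
        out = dp_align_segment(S, T, params)
        matched = [(p.left, p.right) for p in out if not p.is_gap]
        assert matched == [(0, 0)]
        total = pairing_total_score(out, S, T, params)
        assert total == pytest.approx(brute_force_best(S, T, params), abs=1e-9)

    @pytest.mark.parametrize("seed", range(150))
    def test_matches_brute_force_on_random_segments(self, seed):
        params = AlignmentParams()
        rng = np.random.default_rng(seed)
        S = random_segment(rng, int(rng.integers(0, 7)))
        T = random_segment(rng, int(rng.integers(0, 7)))
        out = dp_align_segment(S, T, params)
        total = pairing_total_score(out, S, T, params)
        assert total == pytest.approx(brute_force_best(S, T, params), abs=1e-9)


class TestAlignPair:
    def test_identical_profiles_all_naive(self, params):
        P = make_profile("A", [2.1, 2.5, 3.0])
        Q = make_profile("B", [2.1, 2.5, 3.0])
        out = align_pair(P, Q, params)
        assert all(p.stage == "naive" for p in out)
        assert len(out) == 3

    def test_uniform_small_offset_pairs_via_dp(self, params):
        pos = [2.1, 2.5, 3.0, 3.5]
        P = make_profile("A", pos)
        Q = make_profile("B", [p + 0.01 for p in pos])
        out = align_pair(P, Q, params)
        matched = [(p.left, p.right) for p in out if not p.is_gap]
        assert matched == [(0, 0), (1, 1), (2, 2), (3, 3)]
        assert all(p.stage == "dp" for p in out)  # shift term 0.75 < 0.90

    def test_disjoint_profiles_all_gaps(self, params):
        P = make_profile("A", [2.1, 2.2])
        Q = make_profile("B", [3.1, 3.2])
        out = align_pair(P, Q, params)
        assert all(p.is_gap for p in out) and len(out) == 4

    @pytest.mark.parametrize("seed", range(30))
    def test_invariants_on_random_pairs(self, seed, params):
        rng = np.random.default_rng(1000 + seed)
        P = make_profile("A", np.sort(rng.uniform(2.0, 2.5, 12)),
                         rng.lognormal(np.log(5), 0.6, 12),
                         np.clip(rng.normal(0.004, 0.001, 12), 0.001, None))
        Q = make_profile("B", np.sort(rng.uniform(2.0, 2.5, 12)),
                         rng.lognormal(np.log(5), 0.6, 12),
                         np.clip(rng.normal(0.004, 0.001, 12), 0.001, None))
        out = align_pair(P, Q, params)
        lefts = [p.left for p in out if p.left is not None]
        rights = [p.right for p in out if p.right is not None]
        # conservation: every peak appears exactly once
        assert sorted(lefts) == list(range(12))
        assert sorted(rights) == list(range(12))
        matched = [(p.left, p.right) for p in out if not p.is_gap]
        # no crossover
        assert matched == sorted(matched)
        rs = [r for _, r in matched]
        assert rs == sorted(rs)
        # window and score floor respected
        for i, j in matched:
            assert abs(P.peaks[i].position - Q.peaks[j].position) <= params.m
            assert score(P.peaks[i], Q.peaks[j], params) >= params.min_score - 1e-12

    def test_symmetry_up_to_side_labels(self, params, rng):
        P = make_profile("A", np.sort(rng.uniform(2.0, 2.3, 8)),
                         rng.lognormal(np.log(5), 0.6, 8))
        Q = make_profile("B", np.sort(rng.uniform(2.0, 2.3, 8)),
                         rng.lognormal(np.log(5), 0.6, 8))
        fwd = {(p.left, p.right) for p in align_pair(P, Q, params) if not p.is_gap}
        rev = {(p.right, p.left) for p in align_pair(Q, P, params) if not p.is_gap}
        assert fwd == rev
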