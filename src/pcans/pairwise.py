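"""Pairwise alignment of two peak profiles.

Alignment proceeds in two stages.  First, *naive* alignment anchors pairs of
peaks that are at least ``naive_threshold`` similar in every one of the
three attributes (height, width, position) — these high-identity anchors
partition the remaining peaks into corresponding unaligned segments.
Second, each segment is aligned by a modified dynamic programming scheme:

    c[i][j] = max( c[i-1][j-1] + Scr'(S_i, T_j),
                   c[i-1][j]   + gp,
                   c[i][j-1]   + gp )

where Scr' is the three-attribute similarity unless the candidate pairing
moves a peak further than ``m`` or scores below ``min_score``, in which case
the boundary penalty ``bp`` is substituted, preventing such pairings from
surviving any optimal traceback.  Crossover (shifting a peak over an
adjacent already-aligned peak) is impossible by construction: anchors are
monotone and DP tracebacks are monotone within each segment.

Segments are bounded either by anchored pairs or by "empty" regions where no
cross-profile pair of peaks lies within ``m`` of each other, so no pairing
can straddle a segment boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import attribute_similarities, score
from .types import AlignmentParams, Peak, PeakProfile

__all__ = [
    "PeakPairing",
    "Segment",
    "naive_align",
    "segment_unaligned",
    "dp_align_segment",
    "align_pair",
    "pairing_total_score",
]


@dataclass(frozen=True)
class PeakPairing:
    """One aligned pair or gap.  ``left``/``right`` are peak indices into
    the two profiles (None marks a gap on that side); ``stage`` records which
    stage produced the pairing ('naive', 'dp', or 'gap')."""

    left: int | None
    right: int | None
    stage: str

    @property
    def is_gap(self) -> bool:
        return self.left is None or self.right is None


@dataclass(frozen=True)
class Segment:
    """Corresponding unaligned index ranges (half-open) of the two profiles."""

    left_range: tuple[int, int]
    right_range: tuple[int, int]


def _crossover_free(pairs: list[tuple[int, int]], i: int, j: int) -> bool:
    return all((i < i2) == (j < j2) for i2, j2 in pairs)


def naive_align(
    P: PeakProfile, Q: PeakProfile, params: AlignmentParams
) -> list[PeakPairing]:
    """Anchor pairs whose every attribute similarity reaches the threshold.

    Candidate pairs (within ``m`` of each other) are ranked by weighted
    similarity and accepted greedily, skipping any candidate that would
    reuse a peak or cross an accepted anchor.  Greedy acceptance in
    descending score makes the result deterministic and crossover-free.
    """
    pos_q = Q.positions
    candidates: list[tuple[float, int, int]] = []
    for i, p in enumerate(P.peaks):
        lo = int(np.searchsorted(pos_q, p.position - params.m, side="left"))
        hi = int(np.searchsorted(pos_q, p.position + params.m, side="right"))
        for j in range(lo, hi):
            terms = attribute_similarities(p, Q.peaks[j], params)
            if all(t >= params.naive_threshold for t in terms):
                candidates.append((score(p, Q.peaks[j], params), i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted: list[tuple[int, int]] = []
    used_i: set[int] = set()
    used_j: set[int] = set()
    for _, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        if not _crossover_free(accepted, i, j):
            continue
        accepted.append((i, j))
        used_i.add(i)
        used_j.add(j)
    accepted.sort()
    return [PeakPairing(i, j, "naive") for i, j in accepted]


def segment_unaligned(
    P: PeakProfile,
    Q: PeakProfile,
    anchors: list[PeakPairing],
    params: AlignmentParams,
) -> list[Segment]:
    """Partition unanchored peaks into corresponding segments.

    Within each inter-anchor block, peaks are grouped by cross-profile
    reachability (two peaks on opposite sides connect when within ``m``);
    groups whose ppm spans overlap are merged so each segment maps to
    contiguous index ranges on both sides.  Isolated peaks form singleton
    segments with an empty opposite side (they will simply gap)."""
    anchor_pairs = [(p.left, p.right) for p in anchors]
    blocks = []
    prev_i, prev_j = -1, -1
    for ai, aj in anchor_pairs + [(len(P.peaks), len(Q.peaks))]:
        blocks.append(((prev_i + 1, ai), (prev_j + 1, aj)))
        prev_i, prev_j = ai, aj

    segments: list[Segment] = []
    for (li, hi), (lj, hj) in blocks:
        items = [(P.peaks[i].position, 0, i) for i in range(li, hi)]
        items += [(Q.peaks[j].position, 1, j) for j in range(lj, hj)]
        if not items:
            continue
        items.sort()
        # union-find over items; connect cross-side peaks within m
        parent = list(range(len(items)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a: int, b: int) -> None:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                if items[b][0] - items[a][0] > params.m:
                    break
                if items[a][1] != items[b][1]:
                    union(a, b)
        groups: dict[int, list[int]] = {}
        for a in range(len(items)):
            groups.setdefault(find(a), []).append(a)
        # merge groups whose ppm spans overlap, to keep index ranges contiguous
        spans = sorted(
            (min(items[a][0] for a in g), max(items[a][0] for a in g), g)
            for g in groups.values()
        )
        merged: list[list[int]] = []
        cur_lo, cur_hi, cur = spans[0][0], spans[0][1], list(spans[0][2])
        for lo2, hi2, g in spans[1:]:
            if lo2 <= cur_hi:
                cur.extend(g)
                cur_hi = max(cur_hi, hi2)
            else:
                merged.append(cur)
                cur_lo, cur_hi, cur = lo2, hi2, list(g)
        merged.append(cur)
        for g in merged:
            left = sorted(items[a][2] for a in g if items[a][1] == 0)
            right = sorted(items[a][2] for a in g if items[a][1] == 1)
            lr = (left[0], left[-1] + 1) if left else (li, li)
            rr = (right[0], right[-1] + 1) if right else (lj, lj)
            segments.append(Segment(lr, rr))
    return segments


def _pair_score(s: Peak, t: Peak, params: AlignmentParams) -> float:
    """Scr': similarity, or bp when the pairing violates m or min_score."""
    if abs(s.position - t.position) > params.m:
        return params.bp
    val = score(s, t, params)
    return val if val >= params.min_score else params.bp


def dp_align_segment(
    S_peaks: list[Peak], T_peaks: list[Peak], params: AlignmentParams
) -> list[PeakPairing]:
    """Align one segment by the modified DP recursion and traceback.

    The score matrix borders are initialized as multiples of ``gp`` (linear
    gap accumulation).  Traceback prefers diagonal, then up, then left among
    equal-score moves, maximizing the number of pairings.  A diagonal step
    scored ``bp`` (possible only in pathological parameterizations) is
    emitted as two gaps rather than a forbidden pairing.
    """
    n, mt = len(S_peaks), len(T_peaks)
    scr = np.empty((n, mt))
    for i, s in enumerate(S_peaks):
        for j, t in enumerate(T_peaks):
            scr[i, j] = _pair_score(s, t, params)
    c = np.empty((n + 1, mt + 1))
    c[:, 0] = np.arange(n + 1) * params.gp
    c[0, :] = np.arange(mt + 1) * params.gp
    for i in range(1, n + 1):
        for j in range(1, mt + 1):
            c[i, j] = max(
                c[i - 1, j - 1] + scr[i - 1, j - 1],
                c[i - 1, j] + params.gp,
                c[i, j - 1] + params.gp,
            )
    out: list[PeakPairing] = []
    i, j = n, mt
    eps = 1e-9  # float-robust move identification
    while i > 0 or j > 0:
        if (
            i > 0
            and j > 0
            and abs(c[i, j] - (c[i - 1, j - 1] + scr[i - 1, j - 1])) <= eps
        ):
            if scr[i - 1, j - 1] == params.bp:
                out.append(PeakPairing(None, j - 1, "gap"))
                out.append(PeakPairing(i - 1, None, "gap"))
            else:
                out.append(PeakPairing(i - 1, j - 1, "dp"))
            i, j = i - 1, j - 1
        elif i > 0 and (j == 0 or abs(c[i, j] - (c[i - 1, j] + params.gp)) <= eps):
            out.append(PeakPairing(i - 1, None, "gap"))
            i -= 1
        else:
            out.append(PeakPairing(None, j - 1, "gap"))
            j -= 1
    out.reverse()
    return out


def pairing_total_score(
    pairings: list[PeakPairing],
    S_peaks: list[Peak],
    T_peaks: list[Peak],
    params: AlignmentParams,
) -> float:
    """Realized score of a pairing list: sum of pair similarities plus one
    ``gp`` per gapped peak."""
    total = 0.0
    for p in pairings:
        if p.is_gap:
            total += params.gp
        else:
            total += score(S_peaks[p.left], T_peaks[p.right], params)
    return total


def align_pair(
    P: PeakProfile, Q: PeakProfile, params: AlignmentParams = AlignmentParams()
) -> list[PeakPairing]:
    """Complete two-stage alignment of a profile pair.

    Returns one record per peak of either profile: naive anchors, DP
    pairings, and explicit gaps, sorted left-to-right.  Every non-gap
    pairing respects the movement window ``m`` and the similarity floor.
    """
    anchors = naive_align(P, Q, params)
    segments = segment_unaligned(P, Q, anchors, params)
    all_pairs: list[PeakPairing] = list(anchors)
    for seg in segments:
        s_lo, s_hi = seg.left_range
        t_lo, t_hi = seg.right_range
        local = dp_align_segment(P.peaks[s_lo:s_hi], Q.peaks[t_lo:t_hi], params)
        for pr in local:
            left = None if pr.left is None else pr.left + s_lo
            right = None if pr.right is None else pr.right + t_lo
            all_pairs.append(PeakPairing(left, right, pr.stage))
    all_pairs.sort(
        key=lambda p: (
            P.peaks[p.left].position if p.left is not None else Q.peaks[p.right].position,
            p.left if p.left is not None else -1,
            p.right if p.right is not None else -1,
        )
    )
    return all_pairs
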