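"""Progressive consensus alignment and the single-template baseline.

Profiles are combined pairwise, most-similar pairs first, each aligned pair
being replaced by a *consensus profile*: every successfully aligned pair of
peaks becomes one consensus peak at the median chemical shift of all its
contributing original peaks, with the average height and width of the two
merged peaks; peaks that fail to align pass through unchanged.  Rounds of
pairing and merging repeat until a single consensus remains, which defines
the final aligned position of every original input peak.

Pair choice uses synchronous sample-sample correlation: each profile is
rasterized onto a shared ppm grid (stick spectrum smoothed with a narrow
triangular kernel) and Pearson correlation between the rasters ranks the
candidate pairs.  Correlations are recomputed on the consensus profiles at
every round.

Aligning peaks at their median position makes the consensus robust to
chemical-shift noise, and pass-through ensures group-specific peaks are
never lost — the property that distinguishes this approach from aligning
everything to a single chosen template (also implemented here, as the
comparison baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pairwise import PeakPairing, align_pair
from .types import AlignmentParams, Contributor, Peak, PeakProfile

__all__ = [
    "GuideSchedule",
    "AlignmentResult",
    "profile_correlation",
    "build_schedule",
    "merge_pair",
    "align",
    "align_to_template",
]

#: Rasterization grid step (ppm) and triangular-kernel half-width (ppm) for
#: the sample-sample correlation.  The kernel makes the correlation tolerant
#: of sub-window jitter without blurring distinct peaks together.
GRID_STEP = 0.001
KERNEL_HALF_WIDTH = 0.01


@dataclass
class GuideSchedule:
    """Rounds of profile pairings; a ``(id, None)`` entry marks a bye."""

    rounds: list[list[tuple[str, str | None]]] = field(default_factory=list)


@dataclass
class AlignmentResult:
    """Outcome of a full alignment.

    ``peak_map`` has one row per original input peak with columns
    ``profile_id, peak_id, original_ppm, aligned_ppm, height``;
    ``consensus`` is the final consensus profile (template profile in
    template mode); ``n_unique_aligned`` counts distinct final positions.
    """

    peak_map: pd.DataFrame
    consensus: PeakProfile
    n_unique_aligned: int
    schedule: GuideSchedule = field(default_factory=GuideSchedule)


def _raster_grid(profiles: list[PeakProfile], grid_step: float, pad: float):
    positions = [p.position for prof in profiles for p in prof.peaks]
    if not positions:
        return np.array([0.0, grid_step])
    lo, hi = min(positions) - pad, max(positions) + pad
    n = max(2, int(np.ceil((hi - lo) / grid_step)) + 1)
    return lo + grid_step * np.arange(n)


def _rasterize(
    profile: PeakProfile, grid: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    v = np.zeros(grid.size)
    if profile.peaks:
        step = grid[1] - grid[0]
        idx = np.clip(
            np.round((np.array([p.position for p in profile.peaks]) - grid[0]) / step)
            .astype(int),
            0,
            grid.size - 1,
        )
        np.add.at(v, idx, [p.height for p in profile.peaks])
    return np.convolve(v, kernel, mode="same")


def _triangular_kernel(grid_step: float, half_width: float) -> np.ndarray:
    k = max(1, int(round(half_width / grid_step)))
    ramp = 1.0 - np.abs(np.arange(-k, k + 1)) / (k + 1)
    return ramp / ramp.sum()


def _correlation_matrix(rasters: np.ndarray) -> np.ndarray:
    centered = rasters - rasters.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn("zero-variance raster; correlation defined as 0")
    safe = np.where(zero, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    return np.clip(corr, -1.0, 1.0)


def profile_correlation(
    P: PeakProfile,
    Q: PeakProfile,
    grid_step: float = GRID_STEP,
    kernel_half_width: float = KERNEL_HALF_WIDTH,
) -> float:
    """Pearson correlation of the two profiles' smoothed rasters."""
    grid = _raster_grid([P, Q], grid_step, pad=3 * kernel_half_width)
    kernel = _triangular_kernel(grid_step, kernel_half_width)
    rasters = np.vstack([_rasterize(P, grid, kernel), _rasterize(Q, grid, kernel)])
    return float(_correlation_matrix(rasters)[0, 1])


def _greedy_pairs(corr: np.ndarray) -> tuple[list[tuple[int, int]], int | None]:
    """Greedily pick the highest-correlation pairs; return pairs and the
    index left unpaired (bye), if any."""
    k = corr.shape[0]
    remaining = set(range(k))
    order = np.argsort(corr, axis=None)[::-1]
    pairs: list[tuple[int, int]] = []
    for flat in order:
        a, b = divmod(int(flat), k)
        if a >= b:
            continue
        if a in remaining and b in remaining:
            pairs.append((a, b))
            remaining -= {a, b}
            if len(remaining) < 2:
                break
    bye = remaining.pop() if remaining else None
    return pairs, bye


def merge_pair(
    P: PeakProfile,
    Q: PeakProfile,
    pairings: list[PeakPairing],
    params: AlignmentParams,
    new_profile_id: str | None = None,
) -> PeakProfile:
    """Merge an aligned pair into a consensus profile.

    Each aligned pair of peaks becomes one consensus peak positioned at the
    median of the union of both sides' contributor *original* positions,
    with height and width the means of the two merged peaks' values.
    Unaligned peaks pass through with all attributes unchanged.
    """
    new_id = new_profile_id or f"({P.profile_id}+{Q.profile_id})"
    peaks: list[Peak] = []
    k = 0
    for pr in pairings:
        if pr.is_gap:
            src = P.peaks[pr.left] if pr.left is not None else Q.peaks[pr.right]
            peaks.append(src)
        else:
            p, q = P.peaks[pr.left], Q.peaks[pr.right]
            contributors = p.contributors + q.contributors
            position = float(np.median([c.position for c in contributors]))
            peaks.append(
                Peak(
                    peak_id=f"{new_id}:{k}",
                    position=position,
                    height=(p.height + q.height) / 2.0,
                    width=(p.width + q.width) / 2.0,
                    origin=new_id,
                    contributors=contributors,
                )
            )
            k += 1
    return PeakProfile(new_id, peaks, kind="consensus")


def _progressive_merge(
    profiles: list[PeakProfile],
    params: AlignmentParams,
    grid_step: float,
    kernel_half_width: float,
) -> tuple[PeakProfile, GuideSchedule]:
    current = list(profiles)
    schedule = GuideSchedule()
    kernel = _triangular_kernel(grid_step, kernel_half_width)
    counter = 0
    while len(current) > 1:
        grid = _raster_grid(current, grid_step, pad=3 * kernel_half_width)
        rasters = np.vstack([_rasterize(p, grid, kernel) for p in current])
        corr = _correlation_matrix(rasters)
        pairs, bye = _greedy_pairs(corr)
        round_log: list[tuple[str, str | None]] = []
        next_profiles: list[PeakProfile] = []
        for a, b in pairs:
            P, Q = current[a], current[b]
            counter += 1
            merged = merge_pair(
                P, Q, align_pair(P, Q, params), params, new_profile_id=f"c{counter}"
            )
            next_profiles.append(merged)
            round_log.append((P.profile_id, Q.profile_id))
        if bye is not None:
            next_profiles.append(current[bye])
            round_log.append((current[bye].profile_id, None))
        schedule.rounds.append(round_log)
        current = next_profiles
    return current[0], schedule


def build_schedule(
    profiles: list[PeakProfile],
    params: AlignmentParams = AlignmentParams(),
    grid_step: float = GRID_STEP,
    kernel_half_width: float = KERNEL_HALF_WIDTH,
) -> GuideSchedule:
    """The pairing schedule the progressive alignment would follow.

    Correlations are recomputed on consensus profiles between rounds, so the
    schedule is obtained by actually performing the merges.
    """
    if len(profiles) < 2:
        return GuideSchedule()
    _, schedule = _progressive_merge(profiles, params, grid_step, kernel_half_width)
    return schedule


def _result_from_final(
    profiles: list[PeakProfile], final: PeakProfile, schedule: GuideSchedule
) -> AlignmentResult:
    height_of = {
        (prof.profile_id, pk.peak_id): pk.height
        for prof in profiles
        for pk in prof.peaks
    }
    rows = []
    seen: set[tuple[str, str]] = set()
    for peak in final.peaks:
        for c in peak.contributors:
            key = (c.profile_id, c.peak_id)
            if key in seen:
                raise RuntimeError(f"peak {key} appears in two consensus peaks")
            seen.add(key)
            rows.append(
                {
                    "profile_id": c.profile_id,
                    "peak_id": c.peak_id,
                    "original_ppm": c.position,
                    "aligned_ppm": peak.position,
                    "height": height_of[key],
                }
            )
    if len(seen) != len(height_of):
        raise RuntimeError("alignment lost peaks: contributor sets incomplete")
    peak_map = pd.DataFrame(
        rows, columns=["profile_id", "peak_id", "original_ppm", "aligned_ppm", "height"]
    ).sort_values(["profile_id", "original_ppm"], ignore_index=True)
    n_unique = int(peak_map["aligned_ppm"].round(9).nunique())
    return AlignmentResult(peak_map, final, n_unique, schedule)


def align(
    profiles: list[PeakProfile],
    params: AlignmentParams = AlignmentParams(),
    grid_step: float = GRID_STEP,
    kernel_half_width: float = KERNEL_HALF_WIDTH,
) -> AlignmentResult:
    """Progressive consensus alignment of a set of peak profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    if len(profiles) == 1:
        return _result_from_final(profiles, profiles[0], GuideSchedule())
    final, schedule = _progressive_merge(
        profiles, params, grid_step, kernel_half_width
    )
    return _result_from_final(profiles, final, schedule)


def align_to_template(
    profiles: list[PeakProfile],
    template_id: str,
    params: AlignmentParams = AlignmentParams(),
) -> AlignmentResult:
    """Single-template baseline: align every other profile pairwise to one
    fixed template.

    Differs from the consensus method only in using a representative profile
    as the target: all pairwise steps (naive anchoring, segmentation, DP)
    are identical.  Aligned peaks take the template peak's position;
    unaligned peaks pass through at their original positions (template-less
    regions keep their peaks, but nothing merges them across profiles).
    """
    by_id = {p.profile_id: p for p in profiles}
    if template_id not in by_id:
        raise KeyError(f"unknown template profile {template_id!r}")
    template = by_id[template_id]
    rows = []
    for prof in profiles:
        if prof.profile_id == template_id:
            for pk in prof.peaks:
                rows.append((prof.profile_id, pk.peak_id, pk.position, pk.position, pk.height))
            continue
        pairings = align_pair(template, prof, params)
        for pr in pairings:
            if pr.right is None:
                continue
            pk = prof.peaks[pr.right]
            aligned = template.peaks[pr.left].position if pr.left is not None else pk.position
            rows.append((prof.profile_id, pk.peak_id, pk.position, aligned, pk.height))
    peak_map = pd.DataFrame(
        rows, columns=["profile_id", "peak_id", "original_ppm", "aligned_ppm", "height"]
    ).sort_values(["profile_id", "original_ppm"], ignore_index=True)
    n_unique = int(peak_map["aligned_ppm"].round(9).nunique())
    return AlignmentResult(peak_map, template, n_unique, GuideSchedule())
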