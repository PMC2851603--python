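"""Peak detection for digitized 1D NMR spectra.

A candidate apex is a local maximum of the sampled trace (first difference
changes sign from positive to negative, i.e. zero first derivative with
negative second derivative on the continuous curve) whose contiguous
rise-fall support spans a minimum number of samples.  Candidates are then
filtered by a neighborhood-height rule: a true peak must stand above a set
fraction of the points in a window centered on it.  Each retained peak is
assigned its three attributes: ppm position and intensity at the apex, and
a width at half-height estimated by a triangle fit to the flanks.

No smoothing is applied before differencing: line broadening is expected to
have been applied upstream during spectral processing, and smoothing here
would silently change the method.
"""

from __future__ import annotations

import warnings

import numpy as np

from .types import Peak, PeakProfile, PickingParams, Spectrum

__all__ = [
    "find_candidate_apexes",
    "filter_true_peaks",
    "estimate_width",
    "pick_peaks",
]


def _support_length(y: np.ndarray, apex: int) -> int:
    """Length of the contiguous monotone rise-then-fall run around ``apex``.

    Runs are strict so that flat baseline does not count as part of a peak;
    equal values are admitted only within the apex plateau itself.
    """
    top = y[apex]
    left = apex
    while left > 0 and (y[left - 1] < y[left] or (y[left - 1] == y[left] == top)):
        left -= 1
    right = apex
    n = y.size
    while right < n - 1 and (
        y[right + 1] < y[right] or (y[right + 1] == y[right] == top)
    ):
        right += 1
    return right - left + 1


def find_candidate_apexes(
    spectrum: Spectrum, params: PickingParams = PickingParams()
) -> list[int]:
    """Indices of local maxima with at least ``min_points`` of support.

    Flat-topped maxima (equal-intensity plateaus) yield their midpoint
    sample.  Exact zeros of the derivative are a measure-zero event on
    sampled data, so "zero first derivative" is read as a sign change of the
    first difference from positive to negative.
    """
    y = spectrum.intensity
    if y.size < params.min_points:
        warnings.warn(
            f"spectrum {spectrum.sample_id!r} shorter than min_points; no peaks"
        )
        return []
    d = np.diff(y)
    nz = np.nonzero(d)[0]
    apexes: list[int] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if d[a] > 0 and d[b] < 0:
            apex = (a + 1 + b) // 2  # midpoint of the (possibly flat) top
            if _support_length(y, apex) >= params.min_points:
                apexes.append(apex)
    return apexes


def filter_true_peaks(
    spectrum: Spectrum,
    candidates: list[int],
    params: PickingParams = PickingParams(),
) -> list[int]:
    """Keep candidates whose apex intensity strictly exceeds at least
    ``height_fraction`` of the points in the centered window.

    The window is truncated (not discarded) at the spectrum ends, so peaks
    near the edges are still evaluated.
    """
    y = spectrum.intensity
    half = params.window_points // 2
    kept: list[int] = []
    for i in candidates:
        lo = max(0, i - half)
        hi = min(y.size, i + half + 1)
        window = y[lo:hi]
        n_below = int(np.count_nonzero(window < y[i]))
        if n_below >= params.height_fraction * window.size:
            kept.append(i)
    return kept


def _flank_halfwidth(x: np.ndarray, y: np.ndarray, apex: int, step: int) -> float | None:
    """Half-height half-width on one flank via the triangle side through the
    apex: the secant from the apex sample to the first flank sample below
    half the apex height, evaluated at half height.  None if the flank never
    drops that far (truncated at the spectrum edge or degenerate)."""
    h = y[apex]
    i = apex
    n = y.size
    target = h / 2.0
    while 0 <= i + step < n:
        i += step
        if y[i] < target:
            slope = (h - y[i]) / (x[apex] - x[i])
            return abs(target / slope)
    # flank truncated: fall back to the lowest strictly-lower sample seen
    edge = 0 if step < 0 else n - 1
    if y[edge] < h:
        slope = (h - y[edge]) / (x[apex] - x[edge])
        return abs(target / slope)
    return None


def estimate_width(spectrum: Spectrum, apex_index: int) -> float:
    """Width at half-height (ppm) from a triangle fitted to the peak.

    Each side of the triangle passes through the apex sample and the
    adjacent flank samples; the returned width is the ppm span of the
    triangle's base evaluated at half the apex height.  If one flank is
    truncated at the spectrum boundary, the other flank is mirrored.
    """
    x, y = spectrum.ppm, spectrum.intensity
    if not (0 < apex_index < y.size - 1):
        raise ValueError("apex must have at least one neighbor on each side")
    left = _flank_halfwidth(x, y, apex_index, -1)
    right = _flank_halfwidth(x, y, apex_index, +1)
    if left is None and right is None:
        raise ValueError(f"apex {apex_index}: both flanks degenerate")
    if left is None:
        warnings.warn(f"apex {apex_index}: left flank truncated; mirrored")
        left = right
    if right is None:
        warnings.warn(f"apex {apex_index}: right flank truncated; mirrored")
        right = left
    width = float(left + right)
    if not (width > 0):
        raise ValueError(f"apex {apex_index}: non-positive width estimate")
    return width


def pick_peaks(
    spectrum: Spectrum, params: PickingParams = PickingParams()
) -> PeakProfile:
    """Full picking pipeline: candidates -> height filter -> attributes."""
    candidates = find_candidate_apexes(spectrum, params)
    apexes = filter_true_peaks(spectrum, candidates, params)
    peaks = []
    for k, i in enumerate(apexes):
        peaks.append(
            Peak(
                peak_id=f"{spectrum.sample_id}:{k}",
                position=float(spectrum.ppm[i]),
                height=float(spectrum.intensity[i]),
                width=estimate_width(spectrum, i),
                origin=spectrum.sample_id,
            )
        )
    return PeakProfile(spectrum.sample_id, peaks, kind="leaf")
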