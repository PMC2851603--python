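"""Uniform spectral binning (bucketing) — the classical drift-tolerant
baseline.

The included ppm regions are tiled with half-open ``[low, low + width)``
bins anchored at each region's low edge; a profile's bin value is the sum of
the heights of its peaks falling in the bin.  Raw spectra can be binned the
same way by summing intensity samples.  Bins empty in every profile are
dropped from the output matrix.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .types import BinningParams, PeakProfile, Spectrum

__all__ = ["bin_edges", "bin_profiles", "bin_spectrum"]


def bin_edges(params: BinningParams = BinningParams()) -> np.ndarray:
    """Low edges of all bins across the included regions."""
    edges = []
    for lo, hi in params.included_regions:
        n = int(np.ceil((hi - lo) / params.bin_width))
        edges.extend(lo + params.bin_width * np.arange(n))
    return np.array(edges)


def _assign(positions: np.ndarray, params: BinningParams) -> np.ndarray:
    """Bin index for each position; -1 for positions outside all regions."""
    out = np.full(positions.size, -1, dtype=int)
    offset = 0
    for lo, hi in params.included_regions:
        n = int(np.ceil((hi - lo) / params.bin_width))
        inside = (positions >= lo) & (positions < hi)
        idx = np.floor((positions[inside] - lo) / params.bin_width).astype(int)
        out[inside] = offset + np.minimum(idx, n - 1)
        offset += n
    return out


def bin_profiles(
    profiles: Iterable[PeakProfile], params: BinningParams = BinningParams()
) -> pd.DataFrame:
    """Profiles-by-bins feature matrix; columns labeled by bin low edge.

    Conservation holds by construction: each profile's row sum equals the
    total height of its peaks inside the included regions.
    """
    profiles = list(profiles)
    edges = bin_edges(params)
    mat = np.zeros((len(profiles), edges.size))
    for r, prof in enumerate(profiles):
        if not prof.peaks:
            continue
        pos = prof.positions
        heights = np.array([p.height for p in prof.peaks])
        idx = _assign(pos, params)
        keep = idx >= 0
        np.add.at(mat[r], idx[keep], heights[keep])
    df = pd.DataFrame(
        mat, index=[p.profile_id for p in profiles], columns=np.round(edges, 6)
    )
    occupied = df.columns[(df != 0).any(axis=0)]
    return df[occupied]


def bin_spectrum(
    spectrum: Spectrum, params: BinningParams = BinningParams()
) -> pd.Series:
    """Bin a raw spectrum by summing intensity samples per bin."""
    edges = bin_edges(params)
    idx = _assign(spectrum.ppm, params)
    vals = np.zeros(edges.size)
    keep = idx >= 0
    np.add.at(vals, idx[keep], spectrum.intensity[keep])
    return pd.Series(vals, index=np.round(edges, 6), name=spectrum.sample_id)
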