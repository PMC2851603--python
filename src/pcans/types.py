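"""Core domain types shared across the package.

A 1D NMR spectrum is reduced to a *peak profile*: an ordered list of peaks,
each described by three attributes — chemical shift position at the apex
(ppm), relative height at the apex, and width at half-height (ppm).  These
three attributes are the entire information content used by the alignment
algorithm; the raw trace is only needed for peak picking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "Peak",
    "PeakProfile",
    "AlignmentParams",
    "PickingParams",
    "BinningParams",
    "Contributor",
]


@dataclass(frozen=True)
class Contributor:
    """Provenance record for a consensus peak: one original (leaf) peak.

    ``position`` is the peak's *original* chemical shift, carried forward
    through every merge so that consensus positions can be recomputed as the
    median over the full contributor multiset.
    """

    profile_id: str
    peak_id: str
    position: float


@dataclass
class Spectrum:
    """A digitized 1D NMR trace: ppm axis plus intensity vector.

    The ppm axis must be strictly monotone; descending input is accepted and
    normalized to ascending order on construction.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D vectors")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"ppm and intensity lengths differ "
                f"({self.ppm.size} vs {self.intensity.size})"
            )
        if self.ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        diffs = np.diff(self.ppm)
        if np.all(diffs < 0):  # descending: normalize
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(diffs > 0):
            raise ValueError(f"ppm axis of {self.sample_id!r} is not strictly monotone")

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass
class Peak:
    """One peak: position (ppm), height (relative intensity), width (ppm).

    ``contributors`` records the original leaf peaks merged into this one;
    a leaf peak is its own single contributor.
    """

    peak_id: str
    position: float
    height: float
    width: float
    origin: str = ""
    contributors: tuple[Contributor, ...] = ()

    def __post_init__(self) -> None:
        if not (self.height > 0):
            raise ValueError(f"peak {self.peak_id!r}: height must be > 0")
        if not (self.width > 0):
            raise ValueError(f"peak {self.peak_id!r}: width must be > 0")
        if not self.contributors:
            self.contributors = (
                Contributor(self.origin, self.peak_id, self.position),
            )


@dataclass
class PeakProfile:
    """An ordered per-sample collection of peaks.

    ``kind`` distinguishes leaf profiles (picked or simulated) from consensus
    profiles produced by merging an aligned pair.
    """

    profile_id: str
    peaks: list[Peak] = field(default_factory=list)
    kind: str = "leaf"  # "leaf" | "consensus"

    def __post_init__(self) -> None:
        if self.kind not in ("leaf", "consensus"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p.position)
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"profile {self.profile_id!r}: duplicate peak ids")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks], dtype=float)


@dataclass(frozen=True)
class AlignmentParams:
    """Tunables of the similarity score and the modified DP recursion.

    - ``m``: maximum allowed chemical-shift movement for any single pairing
      (ppm). Typical values are 0.03-0.04 ppm but the right value is data
      dependent.
    - ``p_h``, ``p_w``, ``p_c``: score weights for height, width and chemical
      shift; non-negative and summing to 1.
    - ``min_score``: minimum weighted similarity for a pairing to stand.
    - ``gp``: gap penalty, the cost of leaving one peak unaligned.
    - ``bp``: boundary penalty substituted for the similarity whenever a
      candidate pairing violates ``m`` or ``min_score``.  It acts as a
      sentinel: any value far below every reachable path difference behaves
      identically, so the default is a large negative number.
    - ``naive_threshold``: per-attribute similarity each of the three terms
      must reach for the naive (anchoring) stage to accept a pairing.
    """

    m: float = 0.04
    p_h: float = 1.0 / 3.0
    p_w: float = 1.0 / 3.0
    p_c: float = 1.0 / 3.0
    min_score: float = 0.60
    gp: float = -0.10
    bp: float = -999.0
    naive_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not (self.m > 0):
            raise ValueError("m must be > 0")
        for name in ("p_h", "p_w", "p_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isclose(self.p_h + self.p_w + self.p_c, 1.0, abs_tol=1e-9):
            raise ValueError("score weights p_h + p_w + p_c must sum to 1")
        if not (0.0 <= self.min_score <= 1.0):
            raise ValueError("min_score must lie in [0, 1]")
        if not (self.bp < self.gp < 0):
            raise ValueError("penalties must satisfy bp < gp < 0")
        if not (0.0 < self.naive_threshold <= 1.0):
            raise ValueError("naive_threshold must lie in (0, 1]")

    def replace(self, **kwargs) -> "AlignmentParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PickingParams:
    """Peak-picking tunables.

    ``min_points`` is the minimum number of samples composing a peak (the
    contiguous rise-fall run around the apex); ``window_points`` the size of
    the surrounding region inspected by the height filter; ``height_fraction``
    the fraction of points in that window the apex must exceed.
    """

    min_points: int = 8
    window_points: int = 151
    height_fraction: float = 0.70

    def __post_init__(self) -> None:
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")
        if self.window_points % 2 != 1 or self.window_points <= self.min_points:
            raise ValueError("window_points must be odd and > min_points")
        if not (0.0 < self.height_fraction < 1.0):
            raise ValueError("height_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class BinningParams:
    """Uniform-binning tunables: bin width and included ppm regions."""

    bin_width: float = 0.04
    included_regions: tuple[tuple[float, float], ...] = ((0.5, 4.7), (4.9, 9.5))

    def __post_init__(self) -> None:
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be > 0")
        regs = tuple(tuple(map(float, r)) for r in self.included_regions)
        object.__setattr__(self, "included_regions", regs)
        prev_hi = -np.inf
        for lo, hi in regs:
            if not (lo < hi):
                raise ValueError(f"degenerate region ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("included regions must be disjoint and ascending")
            prev_hi = hi


def concat_profiles(profiles: Iterable[PeakProfile]) -> list[Peak]:
    """Flatten profiles into one list of peaks (helper for exports)."""
    out: list[Peak] = []
    for prof in profiles:
        out.extend(prof.peaks)
    return out
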