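"""Readers and writers for the package's text formats.

Spectra arrive as two-column delimited text (ppm, intensity) as exported by
typical NMR processing software; peak profiles travel as TSV tables; aligned
feature matrices are written as CSV with a header row of ppm positions so
they can be loaded directly into multivariate tools.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import AlignmentParams, Peak, PeakProfile, Spectrum

__all__ = [
    "read_spectrum",
    "read_profile_table",
    "write_profile_table",
    "write_aligned_matrix",
    "read_params",
]

_SPLIT = re.compile(r"[,\s]+")

#: ppm values are printed with 6 decimals: comfortably below the digital
#: resolution of a 16k-point spectrum (~7e-4 ppm per point at 400 MHz).
PPM_DECIMALS = 6


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column (ppm, intensity) text file into a :class:`Spectrum`.

    Any run of whitespace or commas separates the columns; lines beginning
    with ``#`` and blank lines are ignored.  Descending ppm axes are
    normalized to ascending.
    """
    path = Path(path)
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                ppm.append(float(fields[0]))
                intensity.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    return Spectrum(sample_id or path.stem, np.array(ppm), np.array(intensity))


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column tab-delimited text."""
    with open(path, "w") as fh:
        fh.write("# ppm\tintensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.{PPM_DECIMALS}f}\t{y:.6g}\n")


_PROFILE_COLUMNS = ["profile_id", "peak_id", "position_ppm", "height", "width_ppm"]


def read_profile_table(path: str | Path) -> list[PeakProfile]:
    """Read peak profiles from a TSV with columns
    ``profile_id, peak_id, position_ppm, height, width_ppm``.

    Peaks are re-sorted by position within each profile; missing peak ids
    are generated as ``<profile_id>:<ordinal>``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"profile_id": str, "peak_id": str})
    missing = [c for c in _PROFILE_COLUMNS if c not in df.columns and c != "peak_id"]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    profiles: list[PeakProfile] = []
    for pid, group in df.groupby("profile_id", sort=True):
        peaks = []
        for ordinal, row in enumerate(group.itertuples(index=False)):
            pkid = getattr(row, "peak_id", None)
            if pkid is None or (isinstance(pkid, float) and np.isnan(pkid)):
                pkid = f"{pid}:{ordinal}"
            if not (row.height > 0):
                raise ValueError(
                    f"{path}: profile {pid!r} peak {pkid!r}: height must be > 0"
                )
            if not (row.width_ppm > 0):
                raise ValueError(
                    f"{path}: profile {pid!r} peak {pkid!r}: width must be > 0"
                )
            peaks.append(
                Peak(
                    peak_id=str(pkid),
                    position=float(row.position_ppm),
                    height=float(row.height),
                    width=float(row.width_ppm),
                    origin=str(pid),
                )
            )
        profiles.append(PeakProfile(str(pid), peaks))
    return profiles


def write_profile_table(profiles: Iterable[PeakProfile], path: str | Path) -> None:
    """Write profiles to TSV; inverse of :func:`read_profile_table`."""
    rows = []
    for prof in profiles:
        for peak in prof.peaks:
            rows.append(
                {
                    "profile_id": prof.profile_id,
                    "peak_id": peak.peak_id,
                    "position_ppm": round(peak.position, PPM_DECIMALS),
                    "height": peak.height,
                    "width_ppm": round(peak.width, PPM_DECIMALS),
                }
            )
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, sep="\t", index=False)


def aligned_matrix(peak_map: pd.DataFrame) -> pd.DataFrame:
    """Pivot a peak map (profile_id, aligned_ppm, height) into a
    profiles-by-positions feature matrix.

    Columns are the distinct final aligned positions in ascending ppm order;
    a cell holds the profile's peak height at that position (0 if absent).
    """
    df = peak_map.copy()
    df["aligned_ppm"] = df["aligned_ppm"].round(PPM_DECIMALS)
    mat = df.pivot_table(
        index="profile_id",
        columns="aligned_ppm",
        values="height",
        aggfunc="sum",
        fill_value=0.0,
    )
    return mat.sort_index(axis=1)


def write_aligned_matrix(result, path: str | Path) -> None:
    """Write an :class:`~pcans.consensus.AlignmentResult`'s feature matrix
    as CSV (rows = profiles, header = aligned ppm positions)."""
    aligned_matrix(result.peak_map).to_csv(path)


def write_peak_map(result, path: str | Path) -> None:
    """Write the per-peak original -> aligned position map as TSV."""
    df = result.peak_map[["profile_id", "peak_id", "original_ppm", "aligned_ppm"]]
    df = df.copy()
    for col in ("original_ppm", "aligned_ppm"):
        df[col] = df[col].round(PPM_DECIMALS)
    df.to_csv(path, sep="\t", index=False)


def read_params(path: str | Path) -> AlignmentParams:
    """Read alignment parameters from YAML or flat ``key=value`` text.

    Keys mirror :class:`AlignmentParams` field names; absent keys keep their
    defaults.
    """
    text = Path(path).read_text()
    data: dict = {}
    try:
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
    except yaml.YAMLError:
        pass
    if not data:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = float(value)
    valid = AlignmentParams.__dataclass_fields__.keys()
    unknown = set(data) - set(valid)
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    return AlignmentParams(**{k: float(v) for k, v in data.items()})
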