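"""Band-averaged OD / LD / reduced-LD observables and peak location.

Experimentally, the recovery of the outer wall is followed by averaging
the isotropic optical density and the linear dichroism over a fixed
wavenumber band and plotting the averages against recovery time.  The
same reduction is applied here to computed spectra, per frame of a
simulated assembly trajectory.

The reduced LD of a band is defined as the ratio of the band means,
``ld_r = mean(LD) / mean(A_iso)`` (not the mean of the pointwise ratio);
a pointwise variant is available via ``pointwise=True``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .exciton import ExcitonParams, Spectrum, full_spectrum
from .frames import MoleculeFrame

__all__ = ["BandWindow", "TimePoint", "band_average", "timeseries", "find_peak"]

#: outer-wall band of the experimental spectra (cm^-1)
OW_BAND = (16892.0, 17094.0)
#: wider band used for simulated spectra (cm^-1)
SIM_BAND = (15324.0, 18550.0)


@dataclasses.dataclass(frozen=True)
class BandWindow:
    """Inclusive wavenumber window [lo, hi] in cm^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")

    def mask(self, grid: np.ndarray) -> np.ndarray:
        return (grid >= self.lo) & (grid <= self.hi)


@dataclasses.dataclass(frozen=True)
class TimePoint:
    """Band-averaged observables of one frame/time."""

    t: float
    od: float
    ld: float
    ld_r: float

    def __post_init__(self) -> None:
        if self.od < 0:
            raise ValueError("od must be >= 0")


def band_average(
    spectrum: Spectrum, window: BandWindow, pointwise: bool = False
) -> tuple[float, float, float]:
    """Mean A_iso and LD over the window and their ratio ``ld_r``.

    Window endpoints are inclusive; the grid is not resampled.  Raises if
    no grid point falls inside the window.
    """
    mask = window.mask(spectrum.grid)
    if not np.any(mask):
        raise ValueError(
            f"window [{window.lo}, {window.hi}] contains no grid points"
        )
    od = float(np.mean(spectrum.a_iso[mask]))
    ld = float(np.mean(spectrum.ld[mask]))
    if pointwise:
        ld_r = float(np.nanmean(spectrum.ld_r[mask]))
    else:
        ld_r = ld / od if od > 0 else 0.0
    return od, ld, ld_r


def timeseries(
    frames: Sequence[MoleculeFrame],
    params: ExcitonParams,
    window: BandWindow,
    grid: np.ndarray | None = None,
    times: Sequence[float] | None = None,
    seed: int | None = None,
) -> list[TimePoint]:
    """Band-averaged observables for every frame of a trajectory, in order.

    ``times`` defaults to the frame index.  Each frame gets its own
    disorder stream spawned deterministically from ``seed`` (default:
    ``params.seed``), so the series is reproducible and frames are
    statistically independent.
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if times is None:
        times = np.arange(len(frames), dtype=float)
    if len(times) != len(frames):
        raise ValueError("times must match frames in length")
    base = params.seed if seed is None else seed
    root = np.random.SeedSequence(base)
    points = []
    for t, frame, child in zip(times, frames, root.spawn(len(frames))):
        spec = full_spectrum(frame, params, grid, np.random.default_rng(child))
        od, ld, ld_r = band_average(spec, window)
        points.append(TimePoint(float(t), od, ld, ld_r))
    return points


def timeseries_frame(points: Sequence[TimePoint]) -> pd.DataFrame:
    """TimePoints as a tidy DataFrame (columns t, od, ld, ld_r)."""
    return pd.DataFrame([dataclasses.asdict(p) for p in points])


def find_peak(
    grid: np.ndarray,
    component: np.ndarray,
    window: BandWindow | None = None,
) -> tuple[float, float]:
    """Grid argmax of one spectral component; ties go to lower wavenumber.

    Raises on an all-zero (or empty) selection.
    """
    grid = np.asarray(grid, float)
    component = np.asarray(component, float)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if window is not None:
        mask = window.mask(grid)
        grid, component = grid[mask], component[mask]
        if len(grid) == 0:
            raise ValueError("window contains no grid points")
    if np.all(component <= 0):
        raise ValueError("no peak: spectrum is non-positive everywhere")
    best = int(np.argmax(component))  # argmax returns the first (lowest) maximum
    return float(grid[best]), float(component[best])
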