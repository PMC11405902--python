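"""In-memory containers for centroided MS runs.

A :class:`CentroidSpectrum` is a peak list (parallel m/z / intensity arrays,
m/z ascending) plus the scan metadata the pipeline needs: MS level, scan start
time in minutes, and for MS2 the precursor isolation target, isolation
half-width and collision energy. A :class:`Run` is the time-ordered sequence
of spectra from one acquisition, tagged with its acquisition type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

#: Acquisition type tags understood by the pipeline.
ACQUISITION_TYPES = ("DI-NCE-scan", "LC-PRM", "MS1-QC")


@dataclass
class CentroidSpectrum:
    """One centroided scan.

    Attributes
    ----------
    index : int
        0-based scan index within the run.
    time_min : float
        Scan start time in minutes.
    ms_level : int
        1 or 2.
    mz, intensity : np.ndarray
        Parallel peak arrays; m/z strictly ascending, intensities >= 0.
    precursor_mz : float, optional
        Isolation target m/z (MS2 only).
    isolation_halfwidth : float, optional
        Half of the isolation window width in Th (MS2 only).
    nce : float, optional
        Normalized collision energy in percent (MS2 only).
    """

    index: int
    time_min: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_halfwidth: Optional[float] = None
    nce: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must be parallel")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"scan {self.index}: m/z values must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.index}: negative intensity")
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError(f"scan {self.index}: MS2 spectrum without precursor m/z")

    @property
    def tic(self) -> float:
        """Total ion current: summed intensity of all peaks."""
        return float(self.intensity.sum())

    def intensity_in_window(self, lower: float, upper: float) -> float:
        """Summed intensity of peaks with lower <= m/z <= upper (closed)."""
        lo = np.searchsorted(self.mz, lower, side="left")
        hi = np.searchsorted(self.mz, upper, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    """A time-ordered list of centroided spectra from one acquisition."""

    spectra: Sequence[CentroidSpectrum]
    source: str = ""
    acquisition_type: str = "LC-PRM"

    def __post_init__(self):
        times = [s.time_min for s in self.spectra]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("scan start times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[CentroidSpectrum]:
        return iter(self.spectra)

    def ms_level(self, level: int) -> list[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == level]
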