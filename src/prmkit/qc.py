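"""Charge-state-resolved total-ion-current chromatograms for IP sample QC.

Immunopeptidome preparations should be dominated by +1 to +3 peptide ions;
intense signal at high charge states betrays protein or detergent/polymer
contamination. Each MS1 scan is greedily deisotoped — peaks visited in
descending intensity, candidate charges scored by how many isotope partners
appear at the 13C spacing Δ/z — and the scan's total ion current is split by
inferred charge class (+1 … +7, ≥+8, unknown). This is a QC heuristic, not a
quantitative deconvolution: it classifies signal, it does not report
monoisotopic masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import C13_SHIFT
from .spectra import CentroidSpectrum, Run

__all__ = [
    "IsotopeEnvelope",
    "ChargeClassTrace",
    "CHARGE_CLASSES",
    "assign_isotope_charges",
    "charge_resolved_tic",
]

#: Charge classes of the QC trace; charges >= 8 are pooled, leftovers are unknown.
CHARGE_CLASSES = ("+1", "+2", "+3", "+4", "+5", "+6", "+7", ">=+8", "unknown")


def charge_class(charge: Optional[int]) -> str:
    if charge is None:
        return "unknown"
    return ">=+8" if charge >= 8 else f"+{charge}"


@dataclass
class IsotopeEnvelope:
    """A group of isotope peaks assigned one charge (or left unknown)."""

    seed_mz: float
    charge: Optional[int]
    peak_indices: tuple[int, ...]
    summed_intensity: float


def assign_isotope_charges(
    spectrum: CentroidSpectrum,
    max_charge: int = 12,
    tolerance_ppm: float = 10.0,
    min_isotopes: int = 2,
) -> list[IsotopeEnvelope]:
    """Greedy isotope-envelope charge assignment on one MS1 scan.

    Peaks are visited in descending intensity. For each still-unassigned seed,
    every candidate charge z = 1..max_charge is scored by the number of
    unassigned peaks found at seed + k·Δ13C/z (k = 1, 2, …, consecutive)
    within the ppm tolerance; the z with the most matches wins provided at
    least ``min_isotopes − 1`` partners were found (ties go to the higher z,
    since a low z can alias a subsampled high-z pattern but not vice versa).
    Matched peaks are consumed; peaks without partners become singleton
    unknown envelopes. Every peak lands in exactly one envelope.
    """
    mz = spectrum.mz
    intensity = spectrum.intensity
    n = mz.size
    assigned = np.zeros(n, dtype=bool)
    envelopes: list[IsotopeEnvelope] = []
    for seed in np.argsort(-intensity, kind="stable"):
        if assigned[seed]:
            continue
        tol = mz[seed] * tolerance_ppm * 1e-6
        best_z, best_members = None, ()
        for z in range(1, max_charge + 1):
            spacing = C13_SHIFT / z
            members = [int(seed)]
            k = 1
            while True:
                expect = mz[seed] + k * spacing
                lo = np.searchsorted(mz, expect - tol, side="left")
                hi = np.searchsorted(mz, expect + tol, side="right")
                cand = [j for j in range(lo, hi) if not assigned[j]]
                if not cand:
                    break
                members.append(
                    int(max(cand, key=lambda j: intensity[j]))
                )
                k += 1
            if len(members) >= min_isotopes and (
                best_z is None or len(members) >= len(best_members)
            ):
                # >= keeps the higher z on ties (z ascending loop)
                best_z, best_members = z, tuple(members)
        if best_z is None:
            assigned[seed] = True
            envelopes.append(
                IsotopeEnvelope(float(mz[seed]), None, (int(seed),), float(intensity[seed]))
            )
        else:
            for j in best_members:
                assigned[j] = True
            envelopes.append(
                IsotopeEnvelope(
                    float(mz[seed]),
                    best_z,
                    best_members,
                    float(intensity[list(best_members)].sum()),
                )
            )
    return envelopes


@dataclass
class ChargeClassTrace:
    """Per-scan TIC split by inferred charge class."""

    time_min: np.ndarray
    intensity: dict[str, np.ndarray]  # class -> per-scan summed intensity

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_min, charge_class, intensity) for plotting."""
        rows = []
        for cls in CHARGE_CLASSES:
            for t, v in zip(self.time_min, self.intensity[cls]):
                rows.append({"time_min": t, "charge_class": cls, "intensity": v})
        return pd.DataFrame(rows)

    def total(self) -> np.ndarray:
        return np.sum([self.intensity[c] for c in CHARGE_CLASSES], axis=0)


def charge_resolved_tic(
    run: Run,
    max_charge: int = 12,
    tolerance_ppm: float = 10.0,
    min_isotopes: int = 2,
) -> ChargeClassTrace:
    """Charge-state-resolved TIC chromatogram over a run's MS1 scans.

    Per scan the class intensities sum exactly to the scan TIC (every peak
    belongs to exactly one envelope).
    """
    ms1 = run.ms_level(1)
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    times = np.array([s.time_min for s in ms1])
    traces = {cls: np.zeros(len(ms1)) for cls in CHARGE_CLASSES}
    for i, spec in enumerate(ms1):
        for env in assign_isotope_charges(spec, max_charge, tolerance_ppm, min_isotopes):
            traces[charge_class(env.charge)][i] += env.summed_intensity
    return ChargeClassTrace(times, traces)
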