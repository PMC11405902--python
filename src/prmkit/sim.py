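"""Seeded synthetic-data generation for every acquisition type the pipeline
consumes, with ground-truth records for parameter-recovery testing.

Three generators mirror the three acquisition modes:

* :func:`simulate_nce_scan` — a direct-infusion NCE scan: one targeted-MS2
  spectrum per (NCE grid value, replicate), fragment intensities following
  per-fragment Gaussian collision-energy response curves and the surviving
  precursor following a decreasing sigmoid.
* :func:`simulate_prm_run` — a scheduled LC-PRM run: MS2 scans per target on
  a fixed cycle time, transition intensities = reference pattern × Gaussian
  elution profile × spike level, RT-calibration anchor peptides emitted as
  detectable targets, decoys contributing no signal, and an optional global
  RT distortion (affine + smooth sinusoidal) applied to everything.
* :func:`simulate_ms1_run` — MS1 scans of isotope envelopes at chosen charges
  with geometrically decaying isotope intensities.

Noise is multiplicative Gaussian with a chosen coefficient of variation plus
an additive baseline, driven by a ``numpy`` Generator; identical seeds give
identical runs. The defaults — the 4–42% NCE grid in 2% steps with four
replicates, fragment optima spread over 8–36%, 10% replicate CV, 6–12
transitions per target — emulate the acquisition design the pipeline targets.
Noiseless simulations are exact fixed points of the analyzers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import (
    C13_SHIFT,
    FragmentIon,
    IsotopeLabel,
    LabeledPeptide,
    fragment_ions,
    precursor_mz,
)
from .io import TargetRecord
from .nce import DEFAULT_NCE_GRID, depth_score
from .prm import PrtcAnchorSet, ReferenceSpectrum
from .spectra import CentroidSpectrum, Run

__all__ = [
    "NoiseModel",
    "FragmentationModel",
    "ElutionModel",
    "simulate_nce_scan",
    "simulate_prm_run",
    "simulate_ms1_run",
    "random_peptide",
    "random_fragmentation_model",
]

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class NoiseModel:
    """Multiplicative replicate noise plus additive baseline.

    ``cv`` is the relative standard deviation of the multiplicative factor;
    ``baseline`` is a uniform additive offset applied to every emitted peak.
    ``cv=0, baseline=0`` produces noiseless data.
    """

    cv: float = 0.1
    baseline: float = 0.0

    def apply(self, value: float, rng: np.random.Generator) -> float:
        noisy = value * max(0.0, 1.0 + self.cv * rng.standard_normal()) if self.cv > 0 else value
        return noisy + self.baseline


@dataclass
class FragmentationModel:
    """Gaussian NCE response per fragment plus precursor survival sigmoid.

    Fragment intensity: I(NCE) = amplitude · exp(−(NCE − μ)² / (2σ²)).
    Precursor survival: amplitude / (1 + exp((NCE − midpoint)/slope)).
    """

    fragments: dict[str, tuple[float, float, float]]  # annotation -> (amp, mu, sigma)
    precursor_amplitude: float = 1e6
    precursor_midpoint: float = 18.0
    precursor_slope: float = 4.0

    def fragment_intensity(self, annotation: str, nce: float) -> float:
        amp, mu, sigma = self.fragments[annotation]
        return amp * math.exp(-((nce - mu) ** 2) / (2 * sigma**2))

    def precursor_intensity(self, nce: float) -> float:
        return self.precursor_amplitude / (
            1 + math.exp((nce - self.precursor_midpoint) / self.precursor_slope)
        )

    def true_optimum(
        self, grid: Sequence[float] = DEFAULT_NCE_GRID, depth: int = 5
    ) -> float:
        """Noiseless depth-``depth`` argmax over the grid (the ground truth)."""
        best_nce, best_score = None, -1.0
        for nce in grid:
            vals = sorted(
                (self.fragment_intensity(a, nce) for a in self.fragments), reverse=True
            )
            vals = [v for v in vals if v > 0]
            score = vals[depth - 1] if len(vals) >= depth else 0.0
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12
                and best_nce is not None
                and abs(nce - 30.0) < abs(best_nce - 30.0)
            ):
                best_nce, best_score = nce, score
        return float(best_nce)


def random_peptide(
    rng: np.random.Generator,
    length_range: tuple[int, int] = (8, 15),
    n_labels_range: tuple[int, int] = (0, 3),
    exclude: str = "C",
) -> LabeledPeptide:
    """A random canonical peptide with random standard heavy labels."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    alphabet = [r for r in _RESIDUES if r not in exclude]
    seq = "".join(rng.choice(list(alphabet), size=length))
    labelable = [i + 1 for i, r in enumerate(seq) if r in "VLIAFKR"]
    n_labels = min(int(rng.integers(*n_labels_range, endpoint=True)), len(labelable))
    labels = {
        int(pos): IsotopeLabel.standard(seq[pos - 1])
        for pos in rng.choice(labelable, size=n_labels, replace=False)
    } if n_labels else {}
    return LabeledPeptide(seq, labels)


def isolated_fragments(
    fragments: Sequence[FragmentIon],
    precursor_mz_value: Optional[float] = None,
    min_separation_ppm: float = 30.0,
) -> list[FragmentIon]:
    """Fragments whose m/z is resolvable from every other fragment (and the
    precursor) at the extraction tolerance.

    Near-isobaric transitions are legitimately summed by XIC extraction, so a
    simulation that wants a per-fragment ground truth must only give signal to
    fragments that do not share an extraction window.
    """
    mzs = [f.mz for f in fragments]
    if precursor_mz_value is not None:
        mzs.append(precursor_mz_value)
    out = []
    for f in fragments:
        sep_ppm = min(
            (abs(f.mz - m) / f.mz * 1e6 for m in mzs if m != f.mz), default=np.inf
        )
        if sep_ppm > min_separation_ppm and mzs.count(f.mz) == 1:
            out.append(f)
    return out


def random_fragmentation_model(
    fragments: Sequence[FragmentIon],
    rng: np.random.Generator,
    optimum_range: tuple[float, float] = (8.0, 36.0),
    sigma_range: tuple[float, float] = (4.0, 10.0),
    amplitude_range: tuple[float, float] = (1e4, 1e6),
    precursor_mz_value: Optional[float] = None,
    min_fragment_length: int = 3,
) -> FragmentationModel:
    """Random per-fragment Gaussian responses with optima spread over the grid.

    Fragment optima are drawn per fragment around a shared precursor-level
    center (fragmentation energy is largely a precursor property, with
    fragment-to-fragment scatter), so the depth-5 optimum lands inside
    ``optimum_range``. Only rankable fragments get signal: at least
    ``min_fragment_length`` residues and m/z-isolated from all other fragments
    and the precursor (see :func:`isolated_fragments`), keeping the noiseless
    depth-5 optimum of the model identical to what the analyzer observes.
    """
    center = rng.uniform(*optimum_range)
    usable = [f for f in fragments if f.length >= min_fragment_length]
    usable = isolated_fragments(usable, precursor_mz_value)
    frags = {}
    for f in usable:
        mu = center + rng.normal(0, 2.0)
        sigma = rng.uniform(*sigma_range)
        amp = 10 ** rng.uniform(
            math.log10(amplitude_range[0]), math.log10(amplitude_range[1])
        )
        frags[f.annotation] = (amp, mu, sigma)
    return FragmentationModel(
        frags,
        precursor_amplitude=10 ** rng.uniform(5, 6.5),
        precursor_midpoint=center,
        precursor_slope=4.0,
    )


def _make_spectrum(
    index: int,
    time_min: float,
    peaks: dict[float, float],
    ms_level: int,
    noise: NoiseModel,
    rng: np.random.Generator,
    precursor_mz_value: Optional[float] = None,
    isolation_halfwidth: Optional[float] = None,
    nce: Optional[float] = None,
    min_intensity: float = 1e-9,
) -> CentroidSpectrum:
    noisy = {}
    for mz, inten in peaks.items():
        val = noise.apply(inten, rng)
        if val > min_intensity:
            noisy[mz] = noisy.get(mz, 0.0) + val
    mzs = np.array(sorted(noisy))
    intens = np.array([noisy[m] for m in mzs])
    return CentroidSpectrum(
        index=index,
        time_min=time_min,
        ms_level=ms_level,
        mz=mzs,
        intensity=intens,
        precursor_mz=precursor_mz_value,
        isolation_halfwidth=isolation_halfwidth,
        nce=nce,
    )


def simulate_nce_scan(
    peptide: LabeledPeptide,
    charge: int,
    model: FragmentationModel,
    fragments: Sequence[FragmentIon],
    grid: Sequence[float] = DEFAULT_NCE_GRID,
    replicates: int = 4,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    scan_duration_min: float = 0.005,
) -> tuple[Run, dict]:
    """Simulate a direct-infusion NCE scan for one precursor.

    Emits one targeted-MS2 spectrum per (grid value, replicate) in grid order
    with each fragment at its exact m/z and its model intensity under the
    noise model, plus the surviving precursor peak. Returns the run and a
    ground-truth dict with the noiseless depth-5 optimum.
    """
    if not grid:
        raise ValueError("empty NCE grid")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    prec_mz = precursor_mz(peptide, charge)
    frag_mz = {f.annotation: f.mz for f in fragments}
    spectra = []
    idx = 0
    for nce in grid:
        for _ in range(replicates):
            peaks = {
                frag_mz[a]: model.fragment_intensity(a, nce) for a in model.fragments
            }
            peaks[prec_mz] = model.precursor_intensity(nce)
            spectra.append(
                _make_spectrum(
                    idx, idx * scan_duration_min, peaks, 2, noise, rng,
                    precursor_mz_value=prec_mz, isolation_halfwidth=0.35,
                    nce=float(nce),
                )
            )
            idx += 1
    run = Run(spectra, source=f"sim-nce-{peptide.to_string()}-{charge}",
              acquisition_type="DI-NCE-scan")
    truth = {
        "peptide": peptide.to_string(),
        "charge": charge,
        "true_optimal_nce": model.true_optimum(grid),
        "grid": list(grid),
        "replicates": replicates,
    }
    return run, truth


@dataclass
class ElutionModel:
    """Gaussian chromatographic peak for one simulated target."""

    apex_rt_min: float
    width_s: float = 6.0  # Gaussian sigma, seconds
    spike_level: float = 1.0
    tail_tau_s: float = 0.0  # optional exponential tailing constant

    def profile(self, t_min: np.ndarray) -> np.ndarray:
        dt_s = (np.asarray(t_min) - self.apex_rt_min) * 60.0
        g = np.exp(-(dt_s**2) / (2 * self.width_s**2))
        if self.tail_tau_s > 0:
            decay = np.where(dt_s > 0, np.exp(-dt_s / self.tail_tau_s), 1.0)
            g = np.maximum(g, np.where(dt_s > 0, g.max(initial=0) * decay, 0))
        return self.spike_level * g


@dataclass
class PrmTargetSpec:
    """One simulated LC-PRM target: who, where, how strong."""

    target: TargetRecord
    elution: ElutionModel
    pattern: dict[str, tuple[float, float]]  # annotation -> (mz, relative intensity)
    base_intensity: float = 1e5


def _affine_sine_distortion(shift_min=0.0, scale=1.0, wobble_amp_min=0.0,
                            wobble_period_min=20.0):
    def distort(t):
        return shift_min + scale * t + wobble_amp_min * math.sin(
            2 * math.pi * t / wobble_period_min
        )
    return distort


def simulate_prm_run(
    targets: Sequence[PrmTargetSpec],
    decoys: Sequence[TargetRecord] = (),
    anchor_rts_min: Sequence[float] = (),
    anchor_specs: Optional[Sequence[PrmTargetSpec]] = None,
    rt_shift_min: float = 0.0,
    rt_scale: float = 1.0,
    rt_wobble_amp_min: float = 0.0,
    cycle_time_s: float = 2.0,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    schedule_halfwindow_min: float = 2.0,
) -> tuple[Run, PrtcAnchorSet, dict]:
    """Simulate a scheduled LC-PRM run.

    Each target (and each RT-calibration anchor, emitted as a detectable
    target) gets MS2 scans on the cycle-time grid inside its schedule window;
    transition intensities follow the reference pattern × Gaussian elution ×
    spike level under the noise model. Decoy targets get scans but no signal
    (only baseline noise). The RT distortion (affine shift/scale plus a smooth
    sinusoidal wobble) is applied to all apexes and to the returned anchor
    set's sample coordinates, so alignment can undo it. With an empty target
    list the run is a blank-matrix (mock) acquisition.

    Returns ``(run, anchors, ground_truth)`` where ``anchors`` maps
    reference-run RT to (distorted) sample-run RT.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    distort = _affine_sine_distortion(rt_shift_min, rt_scale, rt_wobble_amp_min)

    anchor_specs = list(anchor_specs or [])
    events = []  # (kind, spec_or_target, true_apex_sample_rt)
    for spec in list(targets) + anchor_specs:
        events.append(("signal", spec, distort(spec.elution.apex_rt_min)))
    for decoy in decoys:
        ref_rt = decoy.expected_rt_min if decoy.expected_rt_min is not None else 30.0
        events.append(("decoy", decoy, distort(ref_rt)))

    spectra = []
    idx = 0
    scan_records = []
    for kind, obj, apex_sample in events:
        target = obj.target if kind == "signal" else obj
        t0 = apex_sample - schedule_halfwindow_min
        n_scans = int(2 * schedule_halfwindow_min * 60.0 / cycle_time_s) + 1
        for k in range(n_scans):
            t = t0 + k * cycle_time_s / 60.0
            if kind == "signal":
                level = obj.elution.spike_level * math.exp(
                    -(((t - apex_sample) * 60.0) ** 2) / (2 * obj.elution.width_s**2)
                )
                peaks = {
                    mz: obj.base_intensity * rel * level
                    for _, (mz, rel) in obj.pattern.items()
                }
            else:
                peaks = {}
            scan_records.append((t, peaks, target))
            idx += 1
    scan_records.sort(key=lambda r: r[0])
    for i, (t, peaks, target) in enumerate(scan_records):
        spectra.append(
            _make_spectrum(
                i, t, peaks, 2, noise, rng,
                precursor_mz_value=target.precursor_mz,
                isolation_halfwidth=target.isolation_halfwidth,
                nce=target.nce,
            )
        )
    run = Run(spectra, source="sim-prm", acquisition_type="LC-PRM")
    anchors = PrtcAnchorSet(
        np.asarray(anchor_rts_min, dtype=float),
        np.array([distort(t) for t in anchor_rts_min]),
    ) if len(anchor_rts_min) >= 2 else None
    truth = {
        "targets": {
            s.target.name: {
                "apex_rt_sample_min": distort(s.elution.apex_rt_min),
                "apex_rt_reference_min": s.elution.apex_rt_min,
                "spike_level": s.elution.spike_level,
            }
            for s in list(targets) + anchor_specs
        },
        "decoys": [d.name for d in decoys],
        "rt_shift_min": rt_shift_min,
        "rt_scale": rt_scale,
    }
    return run, anchors, truth


def make_prm_target(
    peptide: LabeledPeptide,
    charge: int,
    apex_rt_min: float,
    rng: np.random.Generator,
    n_transitions: tuple[int, int] = (6, 12),
    spike_level: float = 1.0,
    base_intensity: float = 1e5,
    width_s: float = 6.0,
) -> PrmTargetSpec:
    """Build a simulated PRM target with a random reference fragment pattern.

    Only m/z-isolated fragments are used (near-isobaric b/y pairs would be
    co-extracted at the XIC tolerance and distort the pattern, the situation
    manual transition deselection handles in real assays).
    """
    prec_mz = precursor_mz(peptide, charge)
    frags = isolated_fragments(fragment_ions(peptide, (1,)), prec_mz)
    n = min(int(rng.integers(*n_transitions, endpoint=True)), len(frags))
    chosen = list(rng.choice(len(frags), size=n, replace=False))
    pattern = {}
    for j in chosen:
        f = frags[j]
        pattern[f.annotation] = (f.mz, float(10 ** rng.uniform(-1.5, 0)))
    # normalize to max 1
    top = max(rel for _, rel in pattern.values())
    pattern = {a: (mz, rel / top) for a, (mz, rel) in pattern.items()}
    target = TargetRecord(
        peptide=peptide,
        charge=charge,
        precursor_mz=precursor_mz(peptide, charge),
        isolation_halfwidth=0.5,
        expected_rt_min=apex_rt_min,
    )
    return PrmTargetSpec(
        target=target,
        elution=ElutionModel(apex_rt_min, width_s=width_s, spike_level=spike_level),
        pattern=pattern,
        base_intensity=base_intensity,
    )


def reference_from_pattern(spec: PrmTargetSpec) -> ReferenceSpectrum:
    """The ideal scoring library implied by a simulated target's pattern."""
    transitions = sorted(
        ((a, mz, rel) for a, (mz, rel) in spec.pattern.items()), key=lambda t: -t[2]
    )
    return ReferenceSpectrum(
        target=spec.target,
        transitions=list(transitions),
        reference_rt_min=spec.elution.apex_rt_min,
        source="sim-reference",
    )


def simulate_ms1_run(
    envelopes: Sequence[tuple[float, int, float, int]],
    scans: int = 5,
    noise: Optional[NoiseModel] = None,
    seed: int = 0,
    scan_interval_min: float = 0.05,
    decay: float = 0.6,
) -> tuple[Run, dict]:
    """Simulate MS1 scans of isotope envelopes.

    ``envelopes`` lists ``(seed m/z, charge, intensity, n_isotopes)``; each
    envelope appears in every scan as peaks at seed + k·Δ13C/z with
    geometrically decaying intensities (ratio ``decay``). Ground truth records
    the charge behind every peak.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    peak_truth = []
    base_peaks = {}
    for seed_mz, z, inten, n_iso in envelopes:
        for k in range(n_iso):
            mz = seed_mz + k * C13_SHIFT / z
            base_peaks[mz] = inten * decay**k
            peak_truth.append({"mz": mz, "charge": z, "intensity": inten * decay**k})
    spectra = []
    for i in range(scans):
        spectra.append(
            _make_spectrum(i, i * scan_interval_min, dict(base_peaks), 1, noise, rng)
        )
    run = Run(spectra, source="sim-ms1", acquisition_type="MS1-QC")
    truth = {
        "envelopes": [
            {"seed_mz": e[0], "charge": e[1], "intensity": e[2], "n_isotopes": e[3]}
            for e in envelopes
        ],
        "peaks": peak_truth,
        "class_intensity_per_scan": _class_sums(envelopes, decay),
    }
    return run, truth


def _class_sums(envelopes, decay) -> dict[str, float]:
    from .qc import charge_class

    sums: dict[str, float] = {}
    for seed_mz, z, inten, n_iso in envelopes:
        total = inten * (1 - decay**n_iso) / (1 - decay) if decay != 1 else inten * n_iso
        cls = charge_class(z)
        sums[cls] = sums.get(cls, 0.0) + total
    return sums
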