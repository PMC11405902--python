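# prmkit

A toolkit for developing and evaluating targeted parallel-reaction-monitoring
(PRM) mass-spectrometry assays, aimed at the detection of low-abundance HLA
class I peptides (neoepitopes) with stable-isotope-labeled (SIL) reference
peptides — and applicable to targeted peptide assays generally.

It covers the data-processing half of assay development:

* **Per-precursor collision-energy optimization.** Direct-infusion targeted-MS2
  scans step the normalized collision energy (NCE) over a 4–42% grid in 2%
  steps, four replicate spectra per step. For each precursor the optimum is the
  grid point maximizing the intensity of the *fifth-most-intense* transition —
  maximizing the chance of later detecting at least five transitions. The gain
  over the standard NCE of 30% is a fold change with an unpaired one-sided
  Welch's *t* test; a precursor counts as improved when the fold change is
  ≥ 1.5 *and* p < 0.05.
* **PRM detection scoring.** Fragment chromatograms are extracted at 7 ppm
  inside a scheduled retention-time window, integrated over shared peak
  boundaries, and the per-transition areas *a* are compared to the SIL
  reference pattern *b* with the normalized spectral contrast angle
  NSA = 1 − (2/π)·arccos(*a*·*b* / ‖*a*‖‖*b*‖).
  Reference RTs are mapped between runs by linear interpolation between the
  two adjacent anchors of a retention-time calibration (PRTC) mixture. A
  target is *detected* only when NSA ≥ 0.85, ≥ 5 transitions are detected,
  and |ΔRT| ≤ 1.5 min; every failed gate is reported as a reason code.
* **Assay design checks.** Neoepitope sequence windows from mutation records
  (21mers centered on SNVs; 10 upstream WT residues plus the mutant tail for
  frameshifts/fusions), enumeration of all variant-overlapping 8–11mers with
  lossless exclusion flags (cysteine, anchor-position rules), SIL panel
  validation (heavy label present, no precursor isolation-window collisions
  within ± 1 m/z, no full sequence containment), and the expected linear
  RT-vs-hydrophobicity-index check with studentized-residual outliers.
* **Charge-state QC.** MS1 scans are greedily deisotoped and each scan's total
  ion current is split by inferred charge (+1 … +7, ≥+8, unknown); intense
  high-charge signal flags protein or polymer contamination in
  immunopeptidome preparations.
* **Seeded simulation.** Generators for all three acquisition types with
  ground truth, written as genuine mzML so the full I/O path is exercised.

## Worked example

Simulate a direct-infusion NCE scan and optimize, then a scheduled PRM run
and score it:

```sh
prmkit simulate --preset nce-scan --seed 11 --out-dir nce
prmkit nce-optimize --mzml nce/nce_scan.mzML --targets nce/targets.tsv --out nce/opt.tsv
# INFO: DLQPETTDL[+7]Y/2: optimum NCE 12% (fold 22.63, p 6.19e-05)

prmkit simulate --preset prm --seed 11 --out-dir prm
prmkit prm-score --mzml prm/prm_run.mzML --targets prm/targets.tsv \
    --reference prm/reference_spectra.tsv --anchors prm/anchors.tsv \
    --out prm/detections.tsv
# INFO: HNDQWR[+10]VSNWM/2: detected (NSA 0.988, 7 transitions)
# INFO: QGF[+10]AMMDGP/2: detected (NSA 0.993, 7 transitions)
```

The first command finds that fragmenting the heavy peptide DLQPETTDL[+7]Y
(`[+7]` marks the ¹³C₆/¹⁵N₁ leucine) at NCE 12% instead of the standard 30%
raises the depth-5 transition signal 22.6-fold (one-sided Welch p = 6.2×10⁻⁵)
— this simulated precursor passes the ≥50%-gain, p < 0.05 improvement gate.
The PRM report (`prm/detections.tsv`) carries one row per target:

```
peptide             charge  nsa     n_detected  delta_rt_min  quantity    detected
HNDQWR[+10]VSNWM    2       0.9884  7           0.033         2867566.3   True
QGF[+10]AMMDGP      2       0.9935  7           0.000         3659610.2   True
```

NSA close to 1 means the fragment-intensity pattern matches the SIL
reference; `quantity` is the summed integrated area of the detected
fragment transitions; `delta_rt_min` is the apex distance from the
anchor-aligned reference RT.

Other subcommands: `make-windows` (mutation records → candidate 8–11mers +
FASTA for external predictors), `design-check` (SIL panel rules, RT~HI fit),
`tic-qc` (charge-resolved TIC table and plot).

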