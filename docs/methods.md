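# Methods

This note documents the models and procedures prmkit implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Mass arithmetic

Peptide monoisotopic mass is the sum of residue masses plus one water;
residue masses and the isotope constants (¹³C−¹²C = 1.00335484 Da,
¹⁵N−¹⁴N = 0.99703489 Da, proton = 1.00727647 Da) live in plain-text resource
files under `src/prmkit/data/` so they can be audited without reading code.
SIL labels are the fully ¹³C/¹⁵N-substituted heavy amino acids available
from synthesis vendors — V(5,1), L/I(6,1), A(3,1), F(9,1), K(6,2), R(6,4),
written (n¹³C, n¹⁵N) — and their shifts are exactly additive on the light
mass. Bracket notation (`DLQPETTDL[+7]Y`) round-trips through the parser;
the nominal integer tag is cross-checked against the composition.

Only b/y fragment series are generated (the ion types monitored in HCD-based
targeted work); a/x/c/z ions, neutral losses and PTMs other than the SIL
labels are out of scope, except carbamidomethyl-cysteine as an optional fixed
modification (default off — the candidate filters exclude cysteine peptides
upstream anyway). Fragment charges default to {1, 2}; which fragment charge
states a lab extracts is instrument- and method-dependent, so it is
configurable. Fragments shorter than 3 residues are generated only on request
and are never ranked: they carry little sequence information and sit in
chemically noisy low-m/z regions.

## mzML I/O

Reading uses a streaming XML parser covering the subset of mzML 1.1.0 that
centroided converter output uses (32/64-bit float arrays, zlib or no
compression, per-scan times in any unit, precursor isolation / selected ion /
activation metadata). Profile-mode spectra are rejected by name of the
offending scan — the extraction model assumes centroids. NCE is read from the
activation metadata when present; because stepped-NCE direct-infusion exports
vary by converter, a sidecar scan-index → NCE table is accepted as an
alternative. The bundled writer emits 64-bit uncompressed mzML and exists so
simulated runs exercise the identical I/O path as real data; its output is
also parsed by Bioconductor's mzR, which one test uses as an independent
round-trip oracle. Times are minutes internally, everywhere.

## Collision-energy optimization

The direct-infusion acquisition measures each grid NCE (default 4–42% in 2%
steps) four times. Per spectrum, a transition's intensity is the summed
intensity of all centroid peaks inside its ±12 ppm window (closed interval;
near-isobaric splits are summed, matching XIC conventions). The
depth-5 score of an NCE is the mean intensity of its fifth-most-intense
eligible transition — eligible meaning ≥3 residues and not the surviving
precursor — and the optimum is the grid argmax. Interpreting "depth 5" as
the fifth-ranked intensity rather than the top-5 sum follows the stated
purpose of the procedure (maximize the chance of detecting at least five
transitions); the top-5-sum variant is available via `mode="top_sum"` for
sensitivity analysis. Ranking is recomputed at every NCE rather than frozen
at a reference NCE. Ties break toward the NCE closest to 30% (the
conservative community default), then lower.

The gain statistic compares the depth-5 per-replicate intensities at the
optimum against NCE 30%: the transition ranked fifth by mean intensity at
each NCE contributes its replicate intensities (n = 4 by default; any n ≥ 2
works), and the test is an unpaired one-sided Welch's *t* with
Welch–Satterthwaite degrees of freedom, H₀ "no improvement". Degenerate
zero-variance inputs: p = 0.5 for equal means, else 0/1 by sign, flagged.
A precursor is *improved* only when fold ≥ 1.5 **and** p < 0.05. p-values
are reported raw, per precursor, with the fixed gate — no multiple-testing
correction, as the gate is a per-assay design decision, not an inference
across precursors.

## PRM detection scoring

RT alignment is piecewise-linear interpolation between the two PRTC anchors
bracketing the reference RT, extrapolating with the terminal segment's slope
outside the anchor range; it is exact at the knots and composing with the
inverse anchor set is the identity. Non-monotone anchor sets are rejected
listing the offenders.

XICs are extracted at ±7 ppm (closed interval) over MS2 scans inside the
aligned RT ± 1.5 min window. When two scheduled precursors' isolation
windows overlap, a scan is assigned to the nearest scheduled precursor m/z;
the scheduled centers are taken to be the distinct isolation targets present
in the run. Peak integration replaces manual curation with a deterministic
rule: apex = maximum of the summed top-ranked traces; boundaries extend from
the apex to the nearest local minimum or the first point at ≤1% of the apex
(that point included); per-transition areas are trapezoidal within the
shared boundaries (intensity·s); a transition is detected when positive on
≥3 consecutive scans inside them. The 3-scan rule is a stand-in for a
human's "is there a real peak" judgment and is deliberately simple.

NSA is computed on raw (untransformed) areas against the top-12 reference
transitions; when the peak is too weak to detect all 12, scoring is limited
to the top-k reference-ranked transitions with k = max(5, number detected).
A square-root-transform option exists (default off) because some ecosystems
apply it. The detection call requires NSA ≥ 0.85, ≥5 detected transitions,
and |apex − aligned RT| ≤ 1.5 min (the same half-window used for
scheduling, configurable); failed gates become machine-readable reason
codes, and nothing is silently dropped. Label-free quantity is the summed
area of detected transitions. An optional outlier rule approximating manual
deselection of interfered transitions (drop one if it raises NSA by >0.05
and ≥5 remain) is off by default and logged when used. MS1 precursor traces
can be extracted for diagnostics but never contribute to the call.

## Assay design

SNV windows are 21mers with the mutated residue centered; at protein termini
the window keeps all available flanking residues rather than discarding the
mutation. Frameshift/fusion windows are up to 10 WT residues upstream of the
site plus the mutant tail truncated at the first stop. All 8–11mers
overlapping a variant position are enumerated (38 for an untruncated SNV
21mer); exclusions — cysteine content, and mutation-at-anchor/outside-TCR
when the WT peptide is itself a predicted binder — are flags, not deletions.
Anchor positions and the TCR-recognition region are per-allele knowledge
supplied via config (TCR region defaults to positions 3..n−1 minus anchors);
the rule is inert without it. Binding prediction is consumed as input
columns (eluted-ligand rank, affinity), never computed.

SIL panels are checked for: a heavy label present (and a labelable residue
at all), pairwise precursor m/z gaps > 2×(±1 Th) at every listed charge
combination, and full unlabeled sequence containment. The RT~HI check is an
OLS fit of observed RT on an externally computed hydrophobicity index
(SSRCalc-style, 100 Å C18 / 0.1% FA settings) with outliers at
|externally studentized residual| > 3; a numerically perfect fit reports no
outliers rather than dividing by a zero residual variance.

## Charge-state QC

Deisotoping is greedy and intensity-descending: for each unassigned seed
peak, candidate charges 1..12 are scored by how many unassigned peaks appear
at consecutive ¹³C/z spacings within 10 ppm; the best-scoring charge with at
least one partner wins, ties to the higher charge (a low charge can alias a
subsampled high-charge pattern, not vice versa). Every peak lands in exactly
one envelope, so per-scan class intensities sum exactly to the TIC. Charges
≥8 are pooled into one class; singletons are "unknown". This is a QC
classification heuristic chosen for determinism and speed, not a
quantitative deconvolution — no averagine fitting, no monoisotopic mass
reporting.

## Simulation

Fragment NCE responses are Gaussians I(NCE) = A·exp(−(NCE−μ)²/2σ²) with
per-fragment optima scattered (σ=2%) around a shared precursor-level center
drawn from 8–36%, response widths 4–10%, amplitudes log-uniform over
10⁴–10⁶; the surviving precursor follows a decreasing sigmoid. Real response
curves are more varied in shape; a custom-curve option exists for
shape-robustness tests. Elution profiles are Gaussians (σ = 6 s) with
optional exponential tailing; PRM runs emit scans on a 2 s cycle inside a
±2 min schedule window; RT distortion is affine plus a smooth sinusoid and
applies equally to targets and anchors. Noise is multiplicative Gaussian
(default CV 10%, clipped at zero) plus an additive baseline; all generators
are driven by one seeded generator and are bit-reproducible.

Simulated signal is only assigned to m/z-isolated fragments (pairwise
>30 ppm apart and away from the precursor): near-isobaric b/y coincidences
are co-extracted at the XIC tolerance, so a per-fragment ground truth is
only well defined for resolvable transitions — in real assays this is what
manual transition deselection handles. Consequently, noiseless simulations
are exact fixed points of the analyzers, which the tests verify.

What the generators do **not** emulate: ion statistics (shot noise),
isotope fine structure, chimeric spectra, matrix interferences, detector
saturation, or peak-shape anomalies. Passing tests therefore demonstrate
the correctness of the processing logic under controlled conditions — not
performance on real immunopeptidome data, where interference and curation
judgment dominate.

## Validation problem sizes

`scripts/acceptance.py` uses: 100 simulated precursors for NCE-optimum
recovery (hit = within one grid step of the noiseless depth-5 argmax);
100 random labeled peptides × all fragments against the pyteomics/NIST mass
oracle; 1000 random vector pairs against the independent contrast-angle
formula; 1000 random group pairs against scipy's Welch test; 50 simulated
LC-PRM runs (40 with two spiked targets and one decoy each, 10 blank-matrix
runs) for sensitivity and false-call counting; 20 simulated MS1 runs for
charge-assignment accuracy and TIC conservation; 51 alignment probes under
a +2 min global shift. These sizes give stable statistics while keeping the
whole script under a minute on one core.

## Known limitations

* The peak-boundary and transition-detection rules are deterministic
  surrogates for expert curation; borderline real peaks will be judged
  differently than a human would.
* No FDR estimation across targets: the workflow is a targeted (Tier-3
  style) assay with per-target evidence, not a discovery search.
* The isolation-width-by-precursor-mass mapping used by instrument method
  editors is vendor- and method-specific; widths are user configuration
  (discrete choices 0.4/0.7/1.0/1.5 Th), not guessed.
* Charge assignment uses the ¹³C channel only and claims no equivalence
  with any vendor deconvolution.
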