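"""Assay-design utilities: neoepitope sequence windows, candidate filters,
SIL panel validation and RT-vs-hydrophobicity linearity checks.

Candidate HLA class I ligands (8–11mers) are enumerated from mutation-bearing
sequence windows: a 21mer centered on the mutated residue for SNVs, or up to
10 wild-type residues upstream of the breakpoint followed by the mutant /
frameshift tail for InDels and fusions. Binding prediction itself is external
(netMHCpan-class tools); predictions arrive as optional input columns.
Filtering is lossless — excluded candidates are flagged with machine-readable
reasons, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .chem import (
    LABELABLE_RESIDUES,
    LabeledPeptide,
    precursor_mz,
)

__all__ = [
    "MutationRecord",
    "CandidatePeptide",
    "SilPanelIssue",
    "RtHiFit",
    "mutant_sequence_window",
    "enumerate_and_filter_candidates",
    "validate_sil_panel",
    "rt_hydrophobicity_check",
]

CANDIDATE_LENGTHS = range(8, 12)  # 8-11mers


@dataclass(frozen=True)
class MutationRecord:
    """A somatic protein-coding mutation in protein space."""

    identifier: str
    wt_sequence: str
    variant_type: str  # "SNV" | "InDel-frameshift" | "fusion"
    position: int  # 1-based; SNV site or last WT residue before breakpoint
    alternate: str  # SNV alternate residue, or mutant/frameshift tail sequence

    def __post_init__(self):
        if not 1 <= self.position <= len(self.wt_sequence):
            raise ValueError(
                f"{self.identifier}: position {self.position} outside protein "
                f"of length {len(self.wt_sequence)}"
            )
        if self.variant_type == "SNV":
            if len(self.alternate) != 1:
                raise ValueError(f"{self.identifier}: SNV alternate must be one residue")
            if self.alternate == self.wt_sequence[self.position - 1]:
                raise ValueError(f"{self.identifier}: SNV alternate equals WT residue")


@dataclass
class WindowResult:
    """A mutated sequence window plus the variant positions inside it."""

    sequence: str
    variant_positions: frozenset[int]  # 1-based within the window
    mutation: MutationRecord


def mutant_sequence_window(
    mutation: MutationRecord, snv_flank: int = 10, upstream_wt: int = 10
) -> WindowResult:
    """Build the mutated sequence window used for ligand prediction.

    SNV: a ``2*snv_flank+1``-mer (21mer) with the mutated residue in the
    middle; near the protein termini the window keeps all available flanking
    residues rather than discarding the mutation (the mutant stays as close
    to center as the protein allows). InDel-frameshift / fusion: up to
    ``upstream_wt`` (10) WT residues upstream of the site, concatenated with
    the mutant tail up to the first stop (``*``).
    """
    seq = mutation.wt_sequence
    pos = mutation.position
    if mutation.variant_type == "SNV":
        left = max(1, pos - snv_flank)
        right = min(len(seq), pos + snv_flank)
        window = (
            seq[left - 1 : pos - 1] + mutation.alternate + seq[pos:right]
        )
        return WindowResult(window, frozenset({pos - left + 1}), mutation)
    if mutation.variant_type in ("InDel-frameshift", "fusion"):
        upstream = seq[max(0, pos - upstream_wt) : pos]
        tail = mutation.alternate.split("*")[0]
        window = upstream + tail
        variant = frozenset(range(len(upstream) + 1, len(window) + 1))
        return WindowResult(window, variant, mutation)
    raise ValueError(f"unknown variant type {mutation.variant_type!r}")


@dataclass
class CandidatePeptide:
    """An 8-11mer candidate ligand with lossless exclusion flags."""

    sequence: str
    start: int  # 1-based within the window
    variant_overlap: bool
    exclusion_reasons: list[str] = field(default_factory=list)
    hla_allele: Optional[str] = None
    el_rank: Optional[float] = None
    affinity_nm: Optional[float] = None

    @property
    def retained(self) -> bool:
        return not self.exclusion_reasons and self.variant_overlap


@dataclass
class FilterConfig:
    """Configuration for the candidate exclusion rules.

    The cysteine rule is always active (free cysteines oxidize and alkylate
    unpredictably, compromising synthesis and detection). The anchor/TCR rule
    needs per-allele knowledge: it fires only when ``wt_is_binder`` is given,
    excluding candidates whose mutation sits at an anchor position or outside
    the TCR recognition region while the corresponding WT peptide is itself a
    predicted binder (such peptides risk WT cross-reactivity or no TCR-visible
    change). ``tcr_region`` defaults to positions 3..n-1 minus anchors.
    """

    exclude_cysteine: bool = True
    wt_is_binder: Optional[bool] = None
    anchor_positions: frozenset[int] = frozenset({2})
    tcr_region: Optional[frozenset[int]] = None

    def tcr_positions(self, length: int) -> frozenset[int]:
        if self.tcr_region is not None:
            return self.tcr_region
        return frozenset(range(3, length)) - self.anchor_positions


def enumerate_and_filter_candidates(
    window: str,
    variant_positions: frozenset[int] | set[int],
    config: Optional[FilterConfig] = None,
) -> list[CandidatePeptide]:
    """Enumerate all 8-11mers overlapping a variant position and flag them.

    An untruncated SNV 21mer yields exactly 8+9+10+11 = 38 variant-overlapping
    candidates. Exclusion rules attach reasons; candidates are retained in the
    output either way.
    """
    if len(window) < min(CANDIDATE_LENGTHS):
        return []
    config = config or FilterConfig()
    variant_positions = frozenset(variant_positions)
    out = []
    for length in CANDIDATE_LENGTHS:
        for start in range(1, len(window) - length + 2):
            covered = frozenset(range(start, start + length))
            overlap = covered & variant_positions
            if not overlap:
                continue
            seq = window[start - 1 : start + length - 1]
            cand = CandidatePeptide(seq, start, variant_overlap=True)
            if config.exclude_cysteine and "C" in seq:
                cand.exclusion_reasons.append("cysteine")
            if config.wt_is_binder:
                mut_in_pep = {p - start + 1 for p in overlap}
                anchors = {a if a > 0 else length + 1 + a for a in config.anchor_positions}
                tcr = config.tcr_positions(length)
                if all(p in anchors or p not in tcr for p in mut_in_pep):
                    cand.exclusion_reasons.append("wt_binder_anchor_or_non_tcr")
            out.append(cand)
    return out


@dataclass(frozen=True)
class SilPanelIssue:
    """One design violation in a SIL reference-peptide panel."""

    issue_class: str  # no-heavy-label | isolation-collision | sequence-containment
    peptides: tuple[str, ...]
    detail: str


def validate_sil_panel(
    panel: Sequence[tuple[LabeledPeptide, Sequence[int]]],
    isolation_halfwidth: float = 1.0,
) -> list[SilPanelIssue]:
    """Check a SIL panel against the three design rules.

    Every peptide must carry at least one heavy label (and have a labelable
    residue at all); no two peptides may fall into the same precursor
    isolation window (m/z gap <= 2x the ±1 Th half-width at any listed charge
    combination); no peptide's unlabeled sequence may contain another's in
    full (the label could not disambiguate shared fragments).
    Order-invariant; pair issues are reported once per unordered pair.
    """
    if not panel:
        raise ValueError("empty panel")
    issues: list[SilPanelIssue] = []
    for pep, _ in panel:
        labelable = [r for r in pep.sequence if r in LABELABLE_RESIDUES]
        if not labelable:
            issues.append(
                SilPanelIssue(
                    "no-heavy-label",
                    (pep.to_string(),),
                    "no labelable residue (V/L/I/A/F/K/R) in sequence",
                )
            )
        elif not pep.labels:
            issues.append(
                SilPanelIssue(
                    "no-heavy-label",
                    (pep.to_string(),),
                    "labelable residues present but no heavy label assigned",
                )
            )
    entries = sorted(
        ((pep, tuple(sorted(set(charges)))) for pep, charges in panel),
        key=lambda e: e[0].to_string(),
    )
    for i, (pa, za) in enumerate(entries):
        for pb, zb in entries[i + 1 :]:
            for zx in za:
                for zy in zb:
                    mza, mzb = precursor_mz(pa, zx), precursor_mz(pb, zy)
                    gap = abs(mza - mzb)
                    if gap <= 2 * isolation_halfwidth:
                        issues.append(
                            SilPanelIssue(
                                "isolation-collision",
                                (pa.to_string(), pb.to_string()),
                                f"z={zx} vs z={zy}: m/z {mza:.4f} vs {mzb:.4f}, "
                                f"gap {gap:.4f} <= {2 * isolation_halfwidth:.2f} Th",
                            )
                        )
            sa, sb = pa.sequence, pb.sequence
            if sa != sb and (sa in sb or sb in sa):
                inner, outer = (pa, pb) if sa in sb else (pb, pa)
                issues.append(
                    SilPanelIssue(
                        "sequence-containment",
                        (outer.to_string(), inner.to_string()),
                        f"{outer.sequence} contains {inner.sequence} in full",
                    )
                )
            elif sa == sb:
                issues.append(
                    SilPanelIssue(
                        "sequence-containment",
                        (pa.to_string(), pb.to_string()),
                        "identical unlabeled sequences",
                    )
                )
    return issues


@dataclass
class RtHiFit:
    """OLS fit of observed RT against the hydrophobicity index."""

    slope: float
    intercept: float
    r_squared: float
    outliers: list[int]  # indices into the input records
    studentized_residuals: np.ndarray


def rt_hydrophobicity_check(
    hydrophobicity_index: Sequence[float],
    observed_rt_min: Sequence[float],
    outlier_threshold: float = 3.0,
) -> RtHiFit:
    """Check the expected linear RT ~ HI relation and flag outliers.

    HI values come from an external sequence-based predictor (SSRCalc-style,
    computed for a 100 Å C18 column in 0.1% formic acid); RT should vary
    linearly with HI, so peptides with |externally studentized residual| above
    ``outlier_threshold`` indicate mis-assigned peaks or anomalous behavior.
    """
    hi = np.asarray(hydrophobicity_index, dtype=float)
    rt = np.asarray(observed_rt_min, dtype=float)
    if hi.size != rt.size:
        raise ValueError("HI and RT arrays must be parallel")
    if hi.size < 3:
        raise ValueError("need at least 3 records for a linear fit")
    model = sm.OLS(rt, sm.add_constant(hi)).fit()
    if model.ssr < 1e-12 * max(1.0, float(np.sum(rt**2))):
        studentized = np.zeros(hi.size)  # perfectly collinear: no outliers
    else:
        studentized = OLSInfluence(model).resid_studentized_external
    outliers = [int(i) for i in np.where(np.abs(studentized) > outlier_threshold)[0]]
    return RtHiFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        outliers=outliers,
        studentized_residuals=np.asarray(studentized, dtype=float),
    )
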