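"""Monoisotopic mass arithmetic for light and stable-isotope-labeled peptides.

Everything downstream of this module — transition extraction, collision-energy
optimization, PRM detection scoring, panel design checks — consumes m/z values
produced here. Only the mass arithmetic a targeted assay needs is implemented:
peptide monoisotopic masses, precursor m/z, singly/multiply protonated b/y
fragment ions, and ppm tolerance windows. SIL (stable-isotope-labeled) residues
carry full 13C/15N substitution of their carbon/nitrogen skeleton; the label
shift is additive on top of the light residue mass.

The residue mass table and label compositions live in plain-text resource
files (``data/residue_masses.tsv``, ``data/isotope_labels.tsv``) so they can
be audited without reading code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "RESIDUE_MASSES",
    "WATER",
    "PROTON",
    "C13_SHIFT",
    "N15_SHIFT",
    "LABEL_COMPOSITIONS",
    "LABELABLE_RESIDUES",
    "IsotopeLabel",
    "LabeledPeptide",
    "FragmentIon",
    "MzWindow",
    "monoisotopic_mass",
    "precursor_mz",
    "fragment_ions",
    "mz_tolerance_window",
]

#: Monoisotopic mass of H2O (Da).
WATER = 18.0105646863
#: Monoisotopic mass of the proton (Da).
PROTON = 1.00727646688
#: 13C minus 12C mass difference (Da).
C13_SHIFT = 1.00335483507
#: 15N minus 14N mass difference (Da).
N15_SHIFT = 0.997034886
#: Carbamidomethylation of cysteine (Da), optional fixed modification.
CARBAMIDOMETHYL = 57.021464


def _load_table(name: str) -> list[list[str]]:
    text = resources.files("prmkit.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


#: Monoisotopic residue masses (Da) for the 20 canonical amino acids.
RESIDUE_MASSES: Mapping[str, float] = {
    r: float(m) for r, m in _load_table("residue_masses.tsv")
}

#: 13C/15N substitution counts for the heavy (SIL) amino acids.
LABEL_COMPOSITIONS: Mapping[str, tuple[int, int]] = {
    r: (int(c), int(n)) for r, c, n in _load_table("isotope_labels.tsv")
}

#: Residues available as heavy amino acids in SIL synthesis.
LABELABLE_RESIDUES = frozenset(LABEL_COMPOSITIONS)


class InvalidSequenceError(ValueError):
    """Sequence contains a non-canonical residue or is empty."""


class InvalidChargeError(ValueError):
    """Charge must be a positive integer."""


@dataclass(frozen=True)
class IsotopeLabel:
    """A heavy-isotope substitution on one residue.

    Parameters
    ----------
    residue : str
        One-letter code of the labeled residue.
    n_13c, n_15n : int
        Number of 13C and 15N substitutions.
    """

    residue: str
    n_13c: int
    n_15n: int

    @property
    def mass_shift(self) -> float:
        """Exact label mass shift in Da."""
        return self.n_13c * C13_SHIFT + self.n_15n * N15_SHIFT

    @property
    def nominal_shift(self) -> int:
        """Integer-Da shift as written in bracket notation, e.g. ``[+7]``."""
        return round(self.mass_shift)

    @classmethod
    def standard(cls, residue: str) -> "IsotopeLabel":
        """The fully substituted heavy amino acid for ``residue``.

        Raises
        ------
        ValueError
            If ``residue`` is not one of the labelable residues.
        """
        if residue not in LABEL_COMPOSITIONS:
            raise ValueError(
                f"no standard heavy amino acid for residue {residue!r}; "
                f"labelable residues are {sorted(LABELABLE_RESIDUES)}"
            )
        c, n = LABEL_COMPOSITIONS[residue]
        return cls(residue, c, n)


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide sequence with optional per-position heavy-isotope labels.

    ``labels`` maps 1-based sequence positions to :class:`IsotopeLabel`
    instances whose residue letter must match the sequence at that position.
    """

    sequence: str
    labels: Mapping[int, IsotopeLabel] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sequence:
            raise InvalidSequenceError("empty sequence")
        bad = [r for r in self.sequence if r not in RESIDUE_MASSES]
        if bad:
            raise InvalidSequenceError(
                f"non-canonical residue(s) {sorted(set(bad))} in {self.sequence!r}"
            )
        for pos, lab in self.labels.items():
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"label position {pos} outside [1, {len(self.sequence)}]"
                )
            if lab.residue != self.sequence[pos - 1]:
                raise ValueError(
                    f"label at position {pos} is for {lab.residue!r} but the "
                    f"sequence has {self.sequence[pos - 1]!r}"
                )
        object.__setattr__(self, "labels", dict(self.labels))

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def parse(cls, text: str) -> "LabeledPeptide":
        """Parse bracket notation like ``DLQPETTDL[+7]Y``.

        A ``[+n]`` tag after a residue marks it as the standard heavy amino
        acid; the nominal shift is cross-checked against the composition.
        """
        seq_chars: list[str] = []
        labels: dict[int, IsotopeLabel] = {}
        i = 0
        while i < len(text):
            ch = text[i]
            if ch == "[":
                j = text.index("]", i)
                if not seq_chars:
                    raise InvalidSequenceError(f"label tag before any residue: {text!r}")
                tag = text[i + 1 : j]
                lab = IsotopeLabel.standard(seq_chars[-1])
                nominal = int(tag.lstrip("+"))
                if nominal != lab.nominal_shift:
                    raise ValueError(
                        f"tag [{tag}] does not match the standard heavy "
                        f"{seq_chars[-1]} shift of +{lab.nominal_shift}"
                    )
                labels[len(seq_chars)] = lab
                i = j + 1
            else:
                seq_chars.append(ch)
                i += 1
        return cls("".join(seq_chars), labels)

    def to_string(self) -> str:
        """Bracket-notation round trip of :meth:`parse`."""
        out = []
        for i, r in enumerate(self.sequence, start=1):
            out.append(r)
            if i in self.labels:
                out.append(f"[+{self.labels[i].nominal_shift}]")
        return "".join(out)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment ion."""

    series: str  # "b" or "y"
    ordinal: int  # 1-based, equals the fragment length in residues
    charge: int
    mz: float

    @property
    def length(self) -> int:
        return self.ordinal

    @property
    def annotation(self) -> str:
        """Skyline-style annotation, e.g. ``y4+`` or ``b7++``."""
        return f"{self.series}{self.ordinal}{'+' * self.charge}"


@dataclass(frozen=True)
class MzWindow:
    """A symmetric m/z tolerance window (closed interval)."""

    center: float
    half_width: float

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width

    def __contains__(self, mz: float) -> bool:
        return self.lower <= mz <= self.upper


def monoisotopic_mass(
    peptide: LabeledPeptide, *, carbamidomethyl: bool = False
) -> float:
    """Neutral monoisotopic mass in Da.

    Sum of residue masses plus one water, plus all heavy-label shifts;
    with ``carbamidomethyl=True`` each cysteine additionally carries the
    fixed +57.021464 Da modification.
    """
    mass = WATER + sum(RESIDUE_MASSES[r] for r in peptide.sequence)
    mass += sum(lab.mass_shift for lab in peptide.labels.values())
    if carbamidomethyl:
        mass += CARBAMIDOMETHYL * peptide.sequence.count("C")
    return mass


def precursor_mz(
    peptide: LabeledPeptide, charge: int, *, carbamidomethyl: bool = False
) -> float:
    """Precursor m/z at the given positive charge state."""
    if not isinstance(charge, int) or charge < 1:
        raise InvalidChargeError(f"charge must be a positive integer, got {charge!r}")
    mass = monoisotopic_mass(peptide, carbamidomethyl=carbamidomethyl)
    return (mass + charge * PROTON) / charge


def fragment_ions(
    peptide: LabeledPeptide,
    fragment_charges: Iterable[int] = (1, 2),
    min_length: int = 3,
    *,
    carbamidomethyl: bool = False,
) -> list[FragmentIon]:
    """b- and y-series fragment ions with label shifts applied per fragment.

    Fragments shorter than ``min_length`` residues are excluded: such
    transitions carry little sequence information and sit in chemically noisy
    low-m/z regions, so targeted assays drop them. The returned list is
    sorted by series (b before y), then ordinal, then charge.
    """
    n = len(peptide)
    if n < 2:
        raise InvalidSequenceError("peptide must have at least 2 residues to fragment")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    charges = sorted(set(fragment_charges))
    if not charges or charges[0] < 1:
        raise InvalidChargeError(f"fragment charges must be >= 1, got {charges}")

    def residue_mass(i: int) -> float:  # i is 1-based
        m = RESIDUE_MASSES[peptide.sequence[i - 1]]
        if i in peptide.labels:
            m += peptide.labels[i].mass_shift
        if carbamidomethyl and peptide.sequence[i - 1] == "C":
            m += CARBAMIDOMETHYL
        return m

    out: list[FragmentIon] = []
    for series in ("b", "y"):
        for k in range(max(1, min_length), n):
            if series == "b":
                neutral = sum(residue_mass(i) for i in range(1, k + 1))
            else:
                neutral = sum(residue_mass(i) for i in range(n - k + 1, n + 1)) + WATER
            for z in charges:
                out.append(
                    FragmentIon(series, k, z, (neutral + z * PROTON) / z)
                )
    return out


def mz_tolerance_window(center: float, ppm: float) -> MzWindow:
    """Symmetric ppm tolerance window around ``center`` m/z."""
    if center <= 0 or ppm <= 0:
        raise ValueError(f"center and ppm must be positive, got {center}, {ppm}")
    return MzWindow(center, center * ppm * 1e-6)


def nominal_label_shift(peptide: LabeledPeptide) -> int:
    """Total integer-Da label shift, as written in bracket notation."""
    return round(sum(lab.mass_shift for lab in peptide.labels.values()))
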