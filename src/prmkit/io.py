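"""Readers and writers for the formats the pipeline touches.

mzML is the only spectral ingestion format; vendor raw conversion is upstream
of this tool. The reader is a streaming xml.etree parser covering the subset
of mzML 1.1.0 that converter output uses for centroided runs: 32/64-bit float
binary arrays, zlib or no compression, per-scan times in any time unit,
precursor isolation/selected-ion/activation metadata. A matching writer
(64-bit, uncompressed) lets simulated runs exercise the identical I/O path as
real data.

Target lists and reports are plain delimited text handled with pandas; target
list columns are compatible in spirit with Skyline transition-list exports.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import (
    FragmentIon,
    IsotopeLabel,
    LabeledPeptide,
    precursor_mz as _precursor_mz,
)
from .spectra import CentroidSpectrum, Run

__all__ = [
    "TargetRecord",
    "read_centroid_run",
    "write_mzml",
    "read_target_list",
    "write_target_list",
    "write_report",
    "read_report",
]

#: Default scheduled-RT half-window in minutes.
DEFAULT_RT_HALFWINDOW_MIN = 1.5
#: Discrete isolation full-widths (Th) offered by the instrument method editor.
ISOLATION_WIDTH_CHOICES = (0.4, 0.7, 1.0, 1.5)


class ProfileModeError(ValueError):
    """Run contains profile-mode spectra; only centroided data is supported."""


@dataclass
class TargetRecord:
    """One targeted precursor: sequence, labels, charge and acquisition hints."""

    peptide: LabeledPeptide
    charge: int
    precursor_mz: float
    isolation_halfwidth: float = 0.7 / 2
    nce: Optional[float] = None
    expected_rt_min: Optional[float] = None
    rt_halfwindow_min: float = DEFAULT_RT_HALFWINDOW_MIN
    fragments: Sequence[FragmentIon] = field(default_factory=tuple)

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def name(self) -> str:
        return f"{self.peptide.to_string()}/{self.charge}"


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value=None, unit=None):
    el = ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name)
    el.set("value", "" if value is None else f"{value}")
    if unit is not None:
        unit_acc, unit_name, unit_ref = unit
        el.set("unitCvRef", unit_ref)
        el.set("unitAccession", unit_acc)
        el.set("unitName", unit_name)
    return el


def _encode_array(values: np.ndarray) -> str:
    data = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(data).decode("ascii")


def write_mzml(run: Run, path, *, profile: bool = False) -> None:
    """Write a run as mzML 1.1.0 (centroid, 64-bit, uncompressed arrays).

    ``profile=True`` tags spectra as profile mode instead; only used to test
    the reader's centroid-mode guard.
    """
    ET.register_namespace("", _MZML_NS)
    root = ET.Element(f"{{{_MZML_NS}}}mzML", version="1.1.0")
    cv_list = ET.SubElement(root, "cvList", count="2")
    ET.SubElement(
        cv_list, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    ET.SubElement(
        cv_list, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")
    soft_list = ET.SubElement(root, "softwareList", count="1")
    soft = ET.SubElement(soft_list, "software", id="prmkit", version="0.1.0")
    _cv(soft, "MS:1000799", "custom unreleased software tool", value="prmkit")
    icl = ET.SubElement(root, "instrumentConfigurationList", count="1")
    ic = ET.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = ET.SubElement(root, "dataProcessingList", count="1")
    dp = ET.SubElement(dpl, "dataProcessing", id="DP1")
    pm = ET.SubElement(dp, "processingMethod", order="1", softwareRef="prmkit")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = ET.SubElement(
        root, "run", id=run.source or "run", defaultInstrumentConfigurationRef="IC1"
    )
    sl = ET.SubElement(
        run_el, "spectrumList", count=str(len(run)), defaultDataProcessingRef="DP1"
    )
    for spec in run:
        sp = ET.SubElement(
            sl,
            "spectrum",
            index=str(spec.index),
            id=f"scan={spec.index + 1}",
            defaultArrayLength=str(spec.mz.size),
        )
        _cv(sp, "MS:1000511", "ms level", value=spec.ms_level)
        if profile:
            _cv(sp, "MS:1000128", "profile spectrum")
        else:
            _cv(sp, "MS:1000127", "centroid spectrum")
        _cv(sp, "MS:1000580", "MSn spectrum")
        scan_list = ET.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", value=repr(spec.time_min),
            unit=("UO:0000031", "minute", "UO"),
        )
        if spec.ms_level == 2:
            plist = ET.SubElement(sp, "precursorList", count="1")
            prec = ET.SubElement(plist, "precursor")
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(
                iso, "MS:1000827", "isolation window target m/z",
                value=repr(spec.precursor_mz), unit=("MS:1000040", "m/z", "MS"),
            )
            hw = spec.isolation_halfwidth if spec.isolation_halfwidth is not None else 0.35
            _cv(
                iso, "MS:1000828", "isolation window lower offset",
                value=repr(hw), unit=("MS:1000040", "m/z", "MS"),
            )
            _cv(
                iso, "MS:1000829", "isolation window upper offset",
                value=repr(hw), unit=("MS:1000040", "m/z", "MS"),
            )
            sil = ET.SubElement(prec, "selectedIonList", count="1")
            ion = ET.SubElement(sil, "selectedIon")
            _cv(
                ion, "MS:1000744", "selected ion m/z",
                value=repr(spec.precursor_mz), unit=("MS:1000040", "m/z", "MS"),
            )
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
            if spec.nce is not None:
                _cv(
                    act, "MS:1000045", "collision energy", value=repr(spec.nce),
                    unit=("UO:0000187", "percent", "UO"),
                )
        bdal = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (spec.mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z", "MS")),
            (
                spec.intensity, "MS:1000515", "intensity array",
                ("MS:1000131", "number of detector counts", "MS"),
            ),
        ):
            encoded = _encode_array(arr)
            bda = ET.SubElement(
                bdal, "binaryDataArray", encodedLength=str(len(encoded))
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name, unit=unit)
            ET.SubElement(bda, "binary").text = encoded

    _strip_ns(root)
    root.set("xmlns", _MZML_NS)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def _strip_ns(el):
    el.tag = el.tag.split("}")[-1]
    for child in el:
        _strip_ns(child)


_TIME_TO_MIN = {
    "minute": 1.0,
    "min": 1.0,
    "second": 1 / 60.0,
    "s": 1 / 60.0,
    "millisecond": 1 / 60000.0,
    "hour": 60.0,
}


def _localname(tag: str) -> str:
    return tag.split("}")[-1]


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    dtype = "<f8"
    compressed = False
    text = ""
    for child in bda:
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":  # 32-bit float
                dtype = "<f4"
            elif acc == "MS:1000523":  # 64-bit float
                dtype = "<f8"
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum_element(el: ET.Element, index: int):
    ms_level = None
    centroid = None
    time_min = 0.0
    prec_mz = iso_hw = nce = None
    arrays: dict[str, np.ndarray] = {}
    for cv in el:
        if _localname(cv.tag) != "cvParam":
            continue
        acc = cv.get("accession")
        if acc == "MS:1000511":
            ms_level = int(cv.get("value"))
        elif acc == "MS:1000127":
            centroid = True
        elif acc == "MS:1000128":
            centroid = False
    for scan in el.iter():
        if _localname(scan.tag) != "scan":
            continue
        for cv in scan:
            if _localname(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
                unit = (cv.get("unitName") or "minute").lower()
                time_min = float(cv.get("value")) * _TIME_TO_MIN.get(unit, 1.0)
        break
    for node in el.iter():
        name = _localname(node.tag)
        if name == "isolationWindow":
            for cv in node:
                acc = cv.get("accession")
                if acc == "MS:1000827":
                    prec_mz = float(cv.get("value"))
                elif acc == "MS:1000828":
                    iso_hw = float(cv.get("value"))
        elif name == "selectedIon" and prec_mz is None:
            for cv in node:
                if cv.get("accession") == "MS:1000744":
                    prec_mz = float(cv.get("value"))
        elif name == "activation":
            for cv in node:
                acc = cv.get("accession")
                cv_name = (cv.get("name") or "").lower()
                if acc == "MS:1000045" or "collision energy" in cv_name:
                    if cv.get("value"):
                        nce = float(cv.get("value"))
        elif name == "binaryDataArray":
            values = _decode_binary_array(node)
            for cv in node:
                acc = cv.get("accession")
                if acc == "MS:1000514":
                    arrays["mz"] = values
                elif acc == "MS:1000515":
                    arrays["intensity"] = values
    return ms_level, centroid, time_min, prec_mz, iso_hw, nce, arrays


def read_centroid_run(
    path,
    acquisition_type: str = "LC-PRM",
    nce_sidecar: Optional[pd.DataFrame] = None,
) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    NCE is taken from the activation metadata when present; stepped-NCE
    direct-infusion exports that lack it can supply a sidecar table with
    columns ``scan_index`` and ``nce`` (converters differ in whether they
    propagate per-scan collision energies).

    Raises
    ------
    ProfileModeError
        If any spectrum is tagged profile mode.
    """
    sidecar = None
    if nce_sidecar is not None:
        sidecar = dict(
            zip(nce_sidecar["scan_index"].astype(int), nce_sidecar["nce"].astype(float))
        )
    spectra = []
    i = 0
    for _, el in ET.iterparse(str(path), events=("end",)):
        if _localname(el.tag) != "spectrum":
            continue
        scan_id = el.get("id", f"index={i}")
        ms_level, centroid, time_min, prec_mz, iso_hw, nce, arrays = (
            _parse_spectrum_element(el, i)
        )
        if centroid is False:
            raise ProfileModeError(
                f"spectrum {scan_id!r} is profile mode; only centroided data is supported"
            )
        if ms_level is None or "mz" not in arrays:
            raise ValueError(f"spectrum {scan_id!r}: missing ms level or m/z array")
        if sidecar is not None and i in sidecar:
            nce = sidecar[i]
        spectra.append(
            CentroidSpectrum(
                index=i,
                time_min=time_min,
                ms_level=ms_level,
                mz=arrays["mz"],
                intensity=arrays.get("intensity", np.zeros_like(arrays["mz"])),
                precursor_mz=prec_mz,
                isolation_halfwidth=iso_hw,
                nce=nce,
            )
        )
        el.clear()
        i += 1
    return Run(spectra, source=str(path), acquisition_type=acquisition_type)


# ---------------------------------------------------------------------------
# Target lists
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = [
    "peptide",
    "charge",
    "precursor_mz",
    "isolation_halfwidth",
    "nce",
    "expected_rt_min",
    "rt_halfwindow_min",
]


def read_target_list(path, *, mz_check_ppm: float = 10.0) -> list[TargetRecord]:
    """Read a delimited target list (TSV or CSV, sniffed by extension).

    Required columns: ``peptide`` (bracket notation for SIL labels) and
    ``charge``. ``precursor_mz`` is recomputed from sequence, labels and
    charge; a stated value deviating more than ``mz_check_ppm`` from the
    computed one raises a consistency error. Missing optional columns get the
    standard defaults (RT half-window 1.5 min).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"peptide", "charge"} - set(df.columns)
    if missing:
        raise ValueError(f"target list missing required column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        pep = LabeledPeptide.parse(str(row.peptide))
        charge = int(row.charge)
        mz = _precursor_mz(pep, charge)
        stated = getattr(row, "precursor_mz", None)
        if stated is not None and np.isfinite(stated):
            ppm_dev = abs(stated - mz) / mz * 1e6
            if ppm_dev > mz_check_ppm:
                raise ValueError(
                    f"{row.peptide}/{charge}: stated precursor m/z {stated} deviates "
                    f"{ppm_dev:.1f} ppm from computed {mz:.4f} (> {mz_check_ppm} ppm)"
                )
        records.append(
            TargetRecord(
                peptide=pep,
                charge=charge,
                precursor_mz=mz,
                isolation_halfwidth=_opt(row, "isolation_halfwidth", 0.7 / 2),
                nce=_opt(row, "nce", None),
                expected_rt_min=_opt(row, "expected_rt_min", None),
                rt_halfwindow_min=_opt(
                    row, "rt_halfwindow_min", DEFAULT_RT_HALFWINDOW_MIN
                ),
            )
        )
    return records


def _opt(row, name, default):
    val = getattr(row, name, None)
    if val is None or (isinstance(val, float) and not np.isfinite(val)):
        return default
    return float(val)


def write_target_list(targets: Sequence[TargetRecord], path) -> None:
    """Write targets as TSV readable by :func:`read_target_list`."""
    rows = []
    for t in targets:
        rows.append(
            {
                "peptide": t.peptide.to_string(),
                "charge": t.charge,
                "precursor_mz": t.precursor_mz,
                "isolation_halfwidth": t.isolation_halfwidth,
                "nce": t.nce,
                "expected_rt_min": t.expected_rt_min,
                "rt_halfwindow_min": t.rt_halfwindow_min,
            }
        )
    write_report(pd.DataFrame(rows, columns=_TARGET_COLUMNS), path)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(table: pd.DataFrame, path) -> None:
    """Write a result table as TSV with stable column order and full float precision."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
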