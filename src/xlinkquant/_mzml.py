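"""Minimal mzML 1.1 codec for centroided MS1 runs.

Only the subset of mzML this package needs is supported: centroided MS1
spectra (m/z + intensity arrays, 32/64-bit floats, uncompressed or zlib)
and MS2 scan headers (retention time, selected-ion m/z, charge state).
Writing always emits uncompressed 64-bit arrays.
"""

from __future__ import annotations

import base64
import re
import struct
import zlib
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterator

import numpy as np

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS accessions used by the codec
_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"

_SCAN_RE = re.compile(r"scan=(\d+)")


class MzMLError(ValueError):
    """Raised for files the codec cannot interpret."""


class SpectrumRecord:
    """Decoded spectrum: enough for MS1 peak lists and MS2 headers."""

    __slots__ = ("scan_number", "ms_level", "rt", "mz", "intensity",
                 "precursor_mz", "charge", "is_profile")

    def __init__(self, scan_number: int, ms_level: int, rt: float,
                 mz: np.ndarray, intensity: np.ndarray,
                 precursor_mz: float | None, charge: int | None,
                 is_profile: bool) -> None:
        self.scan_number = scan_number
        self.ms_level = ms_level
        self.rt = rt
        self.mz = mz
        self.intensity = intensity
        self.precursor_mz = precursor_mz
        self.charge = charge
        self.is_profile = is_profile


def _strip(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _rt_seconds(value: float, unit: str | None) -> float:
    if unit in (None, "", "second", "UO:0000010"):
        return value
    if unit in ("minute", "UO:0000031"):
        return value * 60.0
    if unit in ("millisecond", "UO:0000028"):
        return value / 1000.0
    raise MzMLError(f"unsupported retention-time unit {unit!r}")


def _decode_binary(elem: ET.Element) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (kind, values)."""
    dtype = np.float64
    compressed = False
    kind: str | None = None
    text = ""
    for child in elem.iter():
        tag = _strip(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = np.float32
            elif acc == _ACC_F64:
                dtype = np.float64
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc == _ACC_MZ_ARRAY:
                kind = "mz"
            elif acc == _ACC_INT_ARRAY:
                kind = "intensity"
        elif tag == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem: ET.Element, index: int) -> SpectrumRecord:
    spec_id = elem.get("id", "")
    m = _SCAN_RE.search(spec_id)
    scan_number = int(m.group(1)) if m else index + 1

    ms_level = 1
    is_profile = False
    rt = float("nan")
    precursor_mz: float | None = None
    charge: int | None = None
    mz = np.empty(0)
    intensity = np.empty(0)

    for child in elem:
        tag = _strip(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value", "1"))
            elif acc == _ACC_PROFILE:
                is_profile = True
        elif tag == "scanList":
            for cv in child.iter():
                if _strip(cv.tag) == "cvParam" and cv.get("accession") == _ACC_SCAN_START:
                    rt = _rt_seconds(float(cv.get("value", "nan")),
                                     cv.get("unitName") or cv.get("unitAccession"))
        elif tag == "precursorList":
            for cv in child.iter():
                if _strip(cv.tag) != "cvParam":
                    continue
                acc = cv.get("accession")
                if acc == _ACC_SELECTED_MZ:
                    precursor_mz = float(cv.get("value", "nan"))
                elif acc == _ACC_CHARGE:
                    charge = int(cv.get("value", "0"))
        elif tag == "binaryDataArrayList":
            for arr in child:
                if _strip(arr.tag) != "binaryDataArray":
                    continue
                kind, values = _decode_binary(arr)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    intensity = values
    if mz.shape != intensity.shape:
        raise MzMLError(f"spectrum {spec_id!r}: m/z and intensity arrays differ in length")
    return SpectrumRecord(scan_number, ms_level, rt, mz, intensity,
                          precursor_mz, charge, is_profile)


def iter_spectra(path: str | Path) -> Iterator[SpectrumRecord]:
    """Stream decoded spectra from an mzML file (indexed or plain)."""
    path = Path(path)
    if not path.is_file():
        raise MzMLError(f"cannot read mzML file: {path}")
    index = 0
    try:
        for _event, elem in ET.iterparse(str(path), events=("end",)):
            if _strip(elem.tag) == "spectrum":
                yield _parse_spectrum(elem, index)
                index += 1
                elem.clear()
    except ET.ParseError as exc:
        raise MzMLError(f"malformed mzML in {path}: {exc}") from exc


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{values.size}d", *np.asarray(values, dtype=np.float64))
    ).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "",
        unit: tuple[str, str] | None = None) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    if unit is not None:
        attrs.update({"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]})
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, values: np.ndarray, kind: str) -> None:
    payload = _b64(values)
    arr = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cv(arr, _ACC_F64, "64-bit float")
    _cv(arr, _ACC_NOCOMP, "no compression")
    if kind == "mz":
        _cv(arr, _ACC_MZ_ARRAY, "m/z array", unit=("MS:1000040", "m/z"))
    else:
        _cv(arr, _ACC_INT_ARRAY, "intensity array",
            unit=("MS:1000131", "number of detector counts"))
    ET.SubElement(arr, "binary").text = payload


def write_mzml(path: str | Path, spectra: list[SpectrumRecord], run_id: str) -> None:
    """Write spectra (already ordered as acquired) as plain mzML 1.1."""
    root = ET.Element("mzML", {
        "xmlns": _NS,
        "version": "1.1.0",
        "id": run_id,
    })
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {
        "id": "MS", "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cv_list, "cv", {
        "id": "UO", "fullName": "Unit Ontology",
        "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    run = ET.SubElement(root, "run", {"id": run_id})
    spec_list = ET.SubElement(run, "spectrumList", {"count": str(len(spectra))})

    for i, rec in enumerate(spectra):
        spec = ET.SubElement(spec_list, "spectrum", {
            "index": str(i),
            "id": f"scan={rec.scan_number}",
            "defaultArrayLength": str(rec.mz.size),
        })
        _cv(spec, _ACC_MS_LEVEL, "ms level", str(rec.ms_level))
        _cv(spec, _ACC_CENTROID, "centroid spectrum")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, _ACC_SCAN_START, "scan start time", repr(float(rec.rt)),
            unit=("UO:0000010", "second"))
        if rec.ms_level >= 2 and rec.precursor_mz is not None:
            plist = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            ion_list = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(ion_list, "selectedIon")
            _cv(ion, _ACC_SELECTED_MZ, "selected ion m/z", repr(float(rec.precursor_mz)),
                unit=("MS:1000040", "m/z"))
            if rec.charge is not None:
                _cv(ion, _ACC_CHARGE, "charge state", str(rec.charge))
        arrays = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, rec.mz, "mz")
        _binary_array(arrays, rec.intensity, "intensity")

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(str(path), encoding="utf-8", xml_declaration=True)
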