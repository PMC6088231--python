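"""mzML reading and minimal writing.

The reader turns an mzML 1.1 document (bare or wrapped in ``indexedmzML``;
the index is skipped, the store provides its own random access) into a
:class:`~mzhdf.model.RunData`.  Binary data arrays are mapped to spectral
roles by their CV accessions: MS:1000514 m/z, MS:1000515 intensity,
MS:1000516 charge, and a "non-standard data array" (MS:1000786) whose value
is ``noise`` becomes the per-centroid noise vector.  Unknown array types are
preserved under ``other_arrays``.  Retention times are converted to minutes;
chromatogram elements in the source are ignored (recomputed downstream).

The writer emits a minimal, schema-shaped mzML document sufficient for
round-tripping runs and generating fixtures; full metadata chains
(softwareList, dataProcessing) are out of scope.  Supported array codecs are
32/64-bit little-endian floats, uncompressed or zlib.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import IO

import numpy as np

from .codec import BinaryArrayDescriptor, decode_binary_array, encode_binary_array
from .model import RunData, SpectrumRecord

__all__ = ["MzmlFormatError", "MzmlWarning", "WriteOptions", "parse_mzml", "write_mzml"]

_NS = "http://psi.hupo.org/ms/mzml"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_FILTER = "MS:1000512"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE_STATE = "MS:1000041"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_CHARGE_ARRAY = "MS:1000516"
_ACC_NONSTD_ARRAY = "MS:1000786"
_ACC_INSTRUMENT = "MS:1000031"

_SCAN_RE = re.compile(r"scan=(\d+)")


class MzmlFormatError(ValueError):
    """The document violates the subset of mzML this reader requires."""


class MzmlWarning(UserWarning):
    """Recoverable oddity in an mzML document (dropped precursor, missing unit...)."""


@dataclass(frozen=True)
class WriteOptions:
    """Array encoding for :func:`write_mzml` (64-bit/uncompressed round-trips
    bit-exactly; 32-bit halves size at ~1e-7 relative error)."""

    precision: int = 64
    compression: str = "none"
    indexed: bool = False  # wrap in indexedmzML (index offsets are not emitted)


def _cv_params(elem: ET.Element) -> list[ET.Element]:
    return [c for c in elem if c.tag.endswith("cvParam")]


def _scan_number_from_id(spectrum_id: str, ordinal: int) -> int:
    m = _SCAN_RE.search(spectrum_id or "")
    return int(m.group(1)) if m else ordinal


def _parse_spectrum(elem: ET.Element, ordinal: int) -> SpectrumRecord:
    sid = elem.get("id", "")
    scan_number = _scan_number_from_id(sid, ordinal)
    ms_level = 1
    is_centroid = True
    rt_minutes = 0.0
    filter_string = ""
    precursor_mz: float | None = None
    precursor_charge = 0
    precursor_scan: int | None = None

    for cv in _cv_params(elem):
        acc = cv.get("accession", "")
        if acc == _ACC_MS_LEVEL:
            ms_level = int(float(cv.get("value", "1")))
        elif acc == _ACC_CENTROID:
            is_centroid = True
        elif acc == _ACC_PROFILE:
            is_centroid = False

    for scan in elem.iter(f"{{{_NS}}}scan"):
        for cv in _cv_params(scan):
            acc = cv.get("accession", "")
            if acc == _ACC_SCAN_START:
                value = float(cv.get("value", "0"))
                unit = cv.get("unitName") or cv.get("unitAccession") or ""
                if unit in ("second", "UO:0000010"):
                    rt_minutes = value / 60.0
                elif unit in ("minute", "UO:0000031"):
                    rt_minutes = value
                else:
                    warnings.warn(
                        f"spectrum {sid!r}: scan start time without a unit; "
                        "assuming minutes",
                        MzmlWarning,
                        stacklevel=4,
                    )
                    rt_minutes = value
            elif acc == _ACC_FILTER:
                filter_string = cv.get("value", "")
        break  # first scan element only

    precursors = list(elem.iter(f"{{{_NS}}}precursor"))
    if len(precursors) > 1:
        warnings.warn(
            f"spectrum {sid!r}: {len(precursors)} precursors; keeping the first",
            MzmlWarning,
            stacklevel=4,
        )
    if precursors:
        prec = precursors[0]
        ref = prec.get("spectrumRef", "")
        if ref:
            m = _SCAN_RE.search(ref)
            if m:
                precursor_scan = int(m.group(1))
            else:
                warnings.warn(
                    f"spectrum {sid!r}: unparseable precursor reference {ref!r}",
                    MzmlWarning,
                    stacklevel=4,
                )
        for ion in prec.iter(f"{{{_NS}}}selectedIon"):
            for cv in _cv_params(ion):
                acc = cv.get("accession", "")
                if acc == _ACC_SELECTED_MZ:
                    precursor_mz = float(cv.get("value", "nan"))
                elif acc == _ACC_CHARGE_STATE:
                    precursor_charge = int(float(cv.get("value", "0")))
            break

    arrays: dict[str, np.ndarray] = {}
    other: dict[str, np.ndarray] = {}
    for bda in elem.iter(f"{{{_NS}}}binaryDataArray"):
        precision = 64
        compression = "none"
        role: str | None = None
        accession = None
        for cv in _cv_params(bda):
            acc = cv.get("accession", "")
            if acc == _ACC_F64:
                precision = 64
            elif acc == _ACC_F32:
                precision = 32
            elif acc == _ACC_ZLIB:
                compression = "zlib"
            elif acc == _ACC_NOCOMP:
                compression = "none"
            elif acc == _ACC_MZ_ARRAY:
                role = "mz"
            elif acc == _ACC_INT_ARRAY:
                role = "intensity"
            elif acc == _ACC_CHARGE_ARRAY:
                role = "charge"
            elif acc == _ACC_NONSTD_ARRAY:
                name = cv.get("value", "")
                role = "noise" if name == "noise" else "other"
                accession = acc if role == "other" else None
            elif acc.startswith("MS:") and acc not in (_ACC_F64, _ACC_F32):
                # an array-type accession we do not map
                if role is None:
                    role, accession = "other", acc
        binary = bda.find(f"{{{_NS}}}binary")
        text = (binary.text or "") if binary is not None else ""
        desc = BinaryArrayDescriptor(
            role=role or "other",
            precision=precision,
            compression=compression,
            accession=accession,
        )
        values = decode_binary_array(text.strip(), desc)
        if role in ("mz", "intensity", "noise", "charge"):
            arrays[role] = values
        else:
            other[accession or "unknown"] = values

    if "mz" not in arrays or "intensity" not in arrays:
        raise MzmlFormatError(f"spectrum {sid!r} lacks an m/z or intensity array")

    if ms_level == 1:
        precursor_mz, precursor_charge, precursor_scan = None, 0, None

    return SpectrumRecord(
        scan_number=scan_number,
        ms_level=ms_level,
        retention_time=rt_minutes,
        mz=arrays["mz"],
        intensity=arrays["intensity"],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        precursor_scan=precursor_scan,
        filter_string=filter_string,
        is_centroid=is_centroid,
        noise=arrays.get("noise"),
        charge=arrays.get("charge"),
        other_arrays=other,
    )


def parse_mzml(source: str | IO[bytes] | IO[str]) -> RunData:
    """Read an mzML document (path, file object, or XML text) into a run.

    Accepts the ``indexedmzML`` wrapper transparently.  Spectra are sorted by
    scan number (taken from the ``scan=`` token of the spectrum id, else the
    1-based ordinal).
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        root = ET.fromstring(source)
    else:
        root = ET.parse(source).getroot()

    source_file = ""
    for sf in root.iter(f"{{{_NS}}}sourceFile"):
        source_file = sf.get("name") or sf.get("location") or ""
        break
    instrument_model = ""
    for ic in root.iter(f"{{{_NS}}}instrumentConfiguration"):
        for cv in _cv_params(ic):
            if cv.get("accession") == _ACC_INSTRUMENT:
                instrument_model = cv.get("value", "")
        break

    spectra = [
        _parse_spectrum(elem, ordinal)
        for ordinal, elem in enumerate(root.iter(f"{{{_NS}}}spectrum"), start=1)
    ]
    spectra.sort(key=lambda s: s.scan_number)
    centroid_export = all(s.is_centroid for s in spectra) if spectra else True
    return RunData(
        spectra=spectra,
        source_file=source_file,
        instrument_model=instrument_model,
        centroid_export=centroid_export,
    )


def _sub(parent: ET.Element, tag: str, **attrib: str) -> ET.Element:
    return ET.SubElement(parent, tag, attrib)


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra: str):
    attrib = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrib.update(extra)
    ET.SubElement(parent, "cvParam", attrib)


_MINUTE_UNIT = {
    "unitCvRef": "UO",
    "unitAccession": "UO:0000031",
    "unitName": "minute",
}


def _write_arrays(parent: ET.Element, spectrum: SpectrumRecord, opts: WriteOptions):
    entries: list[tuple[str, np.ndarray]] = [
        ("mz", spectrum.mz),
        ("intensity", spectrum.intensity),
    ]
    if spectrum.noise is not None:
        entries.append(("noise", spectrum.noise))
    if spectrum.charge is not None:
        entries.append(("charge", np.asarray(spectrum.charge, dtype=np.float64)))
    lst = _sub(parent, "binaryDataArrayList", count=str(len(entries)))
    for role, values in entries:
        desc = BinaryArrayDescriptor(
            role=role, precision=opts.precision, compression=opts.compression
        )
        payload = encode_binary_array(values, desc)
        bda = _sub(lst, "binaryDataArray", encodedLength=str(len(payload)))
        if opts.precision == 64:
            _cv(bda, _ACC_F64, "64-bit float")
        else:
            _cv(bda, _ACC_F32, "32-bit float")
        if opts.compression == "zlib":
            _cv(bda, _ACC_ZLIB, "zlib compression")
        else:
            _cv(bda, _ACC_NOCOMP, "no compression")
        if role == "mz":
            _cv(bda, _ACC_MZ_ARRAY, "m/z array")
        elif role == "intensity":
            _cv(bda, _ACC_INT_ARRAY, "intensity array")
        elif role == "charge":
            _cv(bda, _ACC_CHARGE_ARRAY, "charge array")
        else:
            _cv(bda, _ACC_NONSTD_ARRAY, "non-standard data array", value="noise")
        ET.SubElement(bda, "binary").text = payload


def write_mzml(run: RunData, destination=None, options: WriteOptions | None = None) -> str:
    """Serialize *run* as minimal mzML; returns the XML text.

    When *destination* (path or binary file object) is given the document is
    also written there.  ``parse_mzml`` of the output reproduces the run —
    bit-exactly at the default 64-bit/uncompressed encoding.  Arrays under
    ``other_arrays`` are not emitted.
    """
    opts = options or WriteOptions()
    mzml = ET.Element("mzML", {"xmlns": _NS, "version": "1.1.0"})
    cv_list = _sub(mzml, "cvList", count="2")
    _sub(
        cv_list, "cv", id="MS", fullName="PSI-MS",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    _sub(
        cv_list, "cv", id="UO", fullName="UNIT-ONTOLOGY",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = _sub(mzml, "fileDescription")
    fcontent = _sub(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    if run.source_file:
        sfl = _sub(fdesc, "sourceFileList", count="1")
        _sub(sfl, "sourceFile", id="SF1", name=run.source_file, location="")
    icl = _sub(mzml, "instrumentConfigurationList", count="1")
    ic = _sub(icl, "instrumentConfiguration", id="IC1")
    if run.instrument_model:
        _cv(ic, _ACC_INSTRUMENT, "instrument model", value=run.instrument_model)
    run_el = _sub(mzml, "run", id="run1", defaultInstrumentConfigurationRef="IC1")
    sl = _sub(run_el, "spectrumList", count=str(len(run.spectra)),
              defaultDataProcessingRef="DP1")

    for index, s in enumerate(run.spectra):
        sid = f"controllerType=0 controllerNumber=1 scan={s.scan_number}"
        sp = _sub(sl, "spectrum", index=str(index), id=sid,
                  defaultArrayLength=str(s.n_peaks))
        _cv(sp, _ACC_MS_LEVEL, "ms level", value=str(s.ms_level))
        if s.ms_level == 1:
            _cv(sp, "MS:1000579", "MS1 spectrum")
        else:
            _cv(sp, "MS:1000580", "MSn spectrum")
        if s.is_centroid:
            _cv(sp, _ACC_CENTROID, "centroid spectrum")
        else:
            _cv(sp, _ACC_PROFILE, "profile spectrum")
        scan_list = _sub(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = _sub(scan_list, "scan")
        _cv(scan, _ACC_SCAN_START, "scan start time",
            value=repr(float(s.retention_time)), **_MINUTE_UNIT)
        if s.filter_string:
            _cv(scan, _ACC_FILTER, "filter string", value=s.filter_string)
        if s.ms_level > 1 and s.precursor_mz is not None:
            pl = _sub(sp, "precursorList", count="1")
            attrib = {}
            if s.precursor_scan is not None:
                attrib["spectrumRef"] = (
                    f"controllerType=0 controllerNumber=1 scan={s.precursor_scan}"
                )
            prec = _sub(pl, "precursor", **attrib)
            sil = _sub(prec, "selectedIonList", count="1")
            ion = _sub(sil, "selectedIon")
            _cv(ion, _ACC_SELECTED_MZ, "selected ion m/z",
                value=repr(float(s.precursor_mz)),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            if s.precursor_charge:
                _cv(ion, _ACC_CHARGE_STATE, "charge state",
                    value=str(s.precursor_charge))
            _sub(prec, "activation")
        _write_arrays(sp, s, opts)

    if opts.indexed:
        wrapper = ET.Element("indexedmzML", {"xmlns": _NS})
        wrapper.append(mzml)
        _sub(wrapper, "indexListOffset").text = "0"
        document = wrapper
    else:
        document = mzml

    text = ET.tostring(document, encoding="unicode", xml_declaration=True)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text.encode("utf-8"))
        else:
            with open(destination, "wb") as fh:
                fh.write(text.encode("utf-8"))
    return text
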