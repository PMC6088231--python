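"""In-memory model of an LC-MS/MS run.

A run is an ordered list of acquisitions (:class:`SpectrumRecord`), each a
scan with parallel peak vectors — m/z and intensity always, optionally a
per-centroid noise estimate and charge assignment as some vendors provide.
Tandem scans (MS2, MS3, ...) reference the scan whose ion they fragmented,
so a run is also a forest of scan trees (:func:`build_scan_tree`).

Derived traces: the basepeak chromatogram (per-scan maximum intensity against
retention time, PSI-MS MS:1000628) and the total ion current chromatogram
(per-scan summed intensity, MS:1000235).  Retention time is minutes
throughout the package.

:func:`to_peaklist_json` emits the ``[[mz, intensity], ...]`` JSON dialect
consumed by web spectrum viewers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "SpectrumRecord",
    "RunData",
    "ChromatogramRecord",
    "ScanTreeNode",
    "ScanTreeError",
    "validate_run",
    "build_scan_tree",
    "flatten_forest",
    "compute_bpc",
    "compute_tic",
    "to_peaklist_json",
    "content_digest",
]


class ScanTreeError(ValueError):
    """A precursor_scan reference that cannot be placed in the scan forest."""


def _as_f8(x) -> np.ndarray:
    return np.ascontiguousarray(np.asarray(x, dtype=np.float64))


def _arrays_equal(a: np.ndarray | None, b: np.ndarray | None) -> bool:
    if a is None or b is None:
        return a is None and b is None
    return a.shape == b.shape and bool(np.array_equal(a, b))


@dataclass(eq=False)
class SpectrumRecord:
    """One acquisition: scan metadata plus parallel peak arrays.

    ``precursor_charge`` 0 encodes "unknown" (vendor convention).  ``noise``
    and ``charge`` are optional per-centroid vectors of the same length as
    ``mz``.  ``other_arrays`` holds decoded binary arrays whose CV accession
    the package does not map to a role (preserved, not stored in HDF5).
    """

    scan_number: int
    ms_level: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int = 0
    precursor_scan: int | None = None
    filter_string: str = ""
    is_centroid: bool = True
    noise: np.ndarray | None = None
    charge: np.ndarray | None = None
    other_arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = _as_f8(self.mz)
        self.intensity = _as_f8(self.intensity)
        if self.noise is not None:
            self.noise = _as_f8(self.noise)
        if self.charge is not None:
            self.charge = np.ascontiguousarray(np.asarray(self.charge, dtype=np.int32))

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumRecord):
            return NotImplemented
        return (
            self.scan_number == other.scan_number
            and self.ms_level == other.ms_level
            and self.retention_time == other.retention_time
            and self.precursor_mz == other.precursor_mz
            and self.precursor_charge == other.precursor_charge
            and self.precursor_scan == other.precursor_scan
            and self.filter_string == other.filter_string
            and self.is_centroid == other.is_centroid
            and _arrays_equal(self.mz, other.mz)
            and _arrays_equal(self.intensity, other.intensity)
            and _arrays_equal(self.noise, other.noise)
            and _arrays_equal(self.charge, other.charge)
            and set(self.other_arrays) == set(other.other_arrays)
            and all(
                _arrays_equal(v, other.other_arrays[k])
                for k, v in self.other_arrays.items()
            )
        )


@dataclass(eq=False)
class RunData:
    """Ordered collection of spectra plus run-level metadata.

    The lingua franca between the mzML reader, the HDF5 store and the
    synthetic generator.  Spectra are ordered by strictly increasing scan
    number; ``centroid_export`` records whether the run was exported as
    vendor centroids (True) or full profile data.
    """

    spectra: list[SpectrumRecord] = field(default_factory=list)
    source_file: str = ""
    instrument_model: str = ""
    centroid_export: bool = True

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[SpectrumRecord]:
        return iter(self.spectra)

    def scan(self, scan_number: int) -> SpectrumRecord:
        for s in self.spectra:
            if s.scan_number == scan_number:
                return s
        raise KeyError(f"no scan {scan_number} in run")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RunData):
            return NotImplemented
        return (
            self.source_file == other.source_file
            and self.instrument_model == other.instrument_model
            and self.centroid_export == other.centroid_export
            and self.spectra == other.spectra
        )


@dataclass
class ScanTreeNode:
    scan_number: int
    children: list["ScanTreeNode"] = field(default_factory=list)


@dataclass(eq=False)
class ChromatogramRecord:
    """Retention-time-indexed trace (basepeak or total-ion)."""

    role: str  # "bpc" | "tic"
    rt: np.ndarray
    value: np.ndarray
    annotation: "RoleAnnotation | None" = None

    def __post_init__(self) -> None:
        self.rt = _as_f8(self.rt)
        self.value = _as_f8(self.value)

    def __len__(self) -> int:
        return int(self.rt.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChromatogramRecord):
            return NotImplemented
        return (
            self.role == other.role
            and _arrays_equal(self.rt, other.rt)
            and _arrays_equal(self.value, other.value)
        )


def validate_run(run: RunData) -> list[str]:
    """Check every run invariant; return human-readable violations (empty = valid).

    Violations are data, not exceptions: callers decide whether to raise.
    """
    report: list[str] = []
    by_scan: dict[int, SpectrumRecord] = {}
    prev_scan = None
    prev_rt = None
    for s in run.spectra:
        tag = f"scan {s.scan_number}"
        if s.scan_number <= 0:
            report.append(f"{tag}: scan_number must be positive")
        if s.scan_number in by_scan:
            report.append(f"{tag}: duplicate scan number")
        by_scan[s.scan_number] = s
        if prev_scan is not None and s.scan_number <= prev_scan:
            report.append(f"{tag}: scan numbers not strictly increasing")
        prev_scan = s.scan_number
        if s.ms_level < 1:
            report.append(f"{tag}: ms_level must be >= 1")
        if s.retention_time < 0:
            report.append(f"{tag}: negative retention time")
        if prev_rt is not None and s.retention_time < prev_rt:
            report.append(f"{tag}: retention times decrease")
        prev_rt = s.retention_time
        if s.mz.size != s.intensity.size:
            report.append(
                f"{tag}: mz/intensity length mismatch ({s.mz.size} vs {s.intensity.size})"
            )
        if s.noise is not None and s.noise.size != s.mz.size:
            report.append(f"{tag}: noise length != mz length")
        if s.charge is not None and s.charge.size != s.mz.size:
            report.append(f"{tag}: charge length != mz length")
        if s.mz.size > 1 and np.any(np.diff(s.mz) < 0):
            report.append(f"{tag}: mz not sorted ascending")
        if s.intensity.size and float(np.min(s.intensity)) < 0:
            report.append(f"{tag}: negative intensity")
        if s.ms_level == 1:
            if s.precursor_mz is not None:
                report.append(f"{tag}: MS1 scan carries precursor_mz")
            if s.precursor_scan is not None:
                report.append(f"{tag}: MS1 scan carries precursor_scan")
    for s in run.spectra:
        if s.precursor_scan is None:
            continue
        tag = f"scan {s.scan_number}"
        parent = by_scan.get(s.precursor_scan)
        if parent is None:
            report.append(f"{tag}: precursor_scan {s.precursor_scan} not in run")
        elif parent.scan_number >= s.scan_number:
            report.append(f"{tag}: precursor_scan {s.precursor_scan} is not earlier")
        elif parent.ms_level != s.ms_level - 1:
            report.append(
                f"{tag}: precursor_scan ms_level {parent.ms_level} != {s.ms_level - 1}"
            )
    return report


def build_scan_tree(run: RunData) -> list[ScanTreeNode]:
    """Arrange the run's scans into a forest following precursor_scan links.

    MS1 scans (and any scan without a parent reference) become roots; every
    other scan becomes a child of its precursor's node.  Ordering by scan
    number is preserved at every level.  Raises :class:`ScanTreeError` for a
    reference to a missing or later scan.
    """
    nodes: dict[int, ScanTreeNode] = {}
    roots: list[ScanTreeNode] = []
    for s in run.spectra:
        node = ScanTreeNode(s.scan_number)
        nodes[s.scan_number] = node
        if s.precursor_scan is None:
            roots.append(node)
        else:
            parent = nodes.get(s.precursor_scan)
            if parent is None:
                raise ScanTreeError(
                    f"scan {s.scan_number} references precursor scan "
                    f"{s.precursor_scan} which is missing or later"
                )
            parent.children.append(node)
    return roots


def flatten_forest(forest: Sequence[ScanTreeNode]) -> list[int]:
    """Depth-first flatten of the forest.

    For data-dependent acquisitions — where every product scan immediately
    follows the survey scan that selected its precursor, as the synthetic
    generator emits — this is the inverse of :func:`build_scan_tree`: the
    flattened order is exactly the run's scan order.
    """
    out: list[int] = []

    def visit(node: ScanTreeNode) -> None:
        out.append(node.scan_number)
        for child in node.children:
            visit(child)

    for root in forest:
        visit(root)
    return out


def _chromatogram(run: RunData, ms_level: int, reduce, role: str) -> ChromatogramRecord:
    rts = []
    values = []
    for s in run.spectra:
        if s.ms_level != ms_level:
            continue
        rts.append(s.retention_time)
        values.append(reduce(s.intensity) if s.intensity.size else 0.0)
    from .cv import ROLE_TABLE, RoleAnnotation

    accession, name, is_fallback = ROLE_TABLE[role]
    ann = RoleAnnotation(role=role, accession=accession, name=name, is_fallback=is_fallback)
    return ChromatogramRecord(role=role, rt=rts, value=values, annotation=ann)


def compute_bpc(run: RunData, ms_level: int = 1) -> ChromatogramRecord:
    """Basepeak chromatogram: per-scan maximum intensity at *ms_level*.

    Scans with empty peak lists contribute 0, keeping the trace aligned with
    scan indices.  Annotated MS:1000628 "basepeak chromatogram".
    """
    return _chromatogram(run, ms_level, lambda v: float(np.max(v)), "bpc")


def compute_tic(run: RunData, ms_level: int = 1) -> ChromatogramRecord:
    """Total ion current chromatogram: per-scan summed intensity at *ms_level*.

    The sum is accumulated left-to-right over the stored peak order, so the
    result is reproducible to the last bit regardless of array library
    summation strategy.  Annotated MS:1000235 "total ion current
    chromatogram".
    """

    def seq_sum(v: np.ndarray) -> float:
        total = 0.0
        for x in v.tolist():
            total += x
        return total

    return _chromatogram(run, ms_level, seq_sum, "tic")


def to_peaklist_json(spectrum: SpectrumRecord, include_metadata: bool = False) -> str:
    """Serialize a spectrum as viewer-ready JSON.

    Default form is a bare array of ``[mz, intensity]`` pairs in ascending
    m/z (the dialect web spectrum viewers consume).  With
    ``include_metadata=True`` an object wraps the pairs together with
    scan_number, ms_level, precursor_mz and precursor_charge.  Floats are
    emitted at full round-trip precision.
    """
    pairs = [[float(m), float(i)] for m, i in zip(spectrum.mz, spectrum.intensity)]
    if not include_metadata:
        return json.dumps(pairs)
    return json.dumps(
        {
            "scan_number": spectrum.scan_number,
            "ms_level": spectrum.ms_level,
            "precursor_mz": spectrum.precursor_mz,
            "precursor_charge": spectrum.precursor_charge,
            "peaks": pairs,
        }
    )


def content_digest(run: RunData) -> str:
    """SHA-256 digest over the run's full content; used to assert that
    operations taking a run are pure."""
    h = hashlib.sha256()
    h.update(
        repr((run.source_file, run.instrument_model, run.centroid_export)).encode()
    )
    for s in run.spectra:
        h.update(
            repr(
                (
                    s.scan_number,
                    s.ms_level,
                    s.retention_time,
                    s.precursor_mz,
                    s.precursor_charge,
                    s.precursor_scan,
                    s.filter_string,
                    s.is_centroid,
                )
            ).encode()
        )
        h.update(s.mz.tobytes())
        h.update(s.intensity.tobytes())
        if s.noise is not None:
            h.update(b"noise" + s.noise.tobytes())
        if s.charge is not None:
            h.update(b"charge" + s.charge.tobytes())
        for k in sorted(s.other_arrays):
            h.update(k.encode() + s.other_arrays[k].tobytes())
    return h.hexdigest()


# re-exported for type checkers; imported lazily above to avoid a cycle
from .cv import RoleAnnotation  # noqa: E402  (module tail import is deliberate)
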