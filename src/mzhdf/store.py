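"""Self-describing HDF5 storage for mass-spectrometry runs.

Two layouts, chosen at write time and recorded in the file:

``ragged`` (default)
    Every element type (m/z, intensity, noise, per-centroid charge) is one
    variable-length dataset of 64-bit floats at the file root, one row per
    scan, alongside fixed-length per-scan metadata datasets (scan number,
    ms level, retention time, precursor m/z/charge, parent scan, filter
    string) and the derived chromatograms.  A generic HDF5 viewer shows the
    whole run at a glance and any row of any dataset is one read.

``tree``
    One group per scan, nested under its parent acquisition's group — MSⁿ
    scan trees become literal HDF5 group hierarchies — each holding that
    scan's peak datasets and scalar attributes.  This mode lets every
    individual element be annotated independently.

Every dataset carries the PSI-MS controlled-vocabulary term that best
describes it, written in both conventions: ``PSI-MS_ID`` / ``PSI-MS_NAME``
attribute pairs, and an attribute whose key is the accession itself (the
``bpc`` dataset has an attribute ``MS:1000628`` = "basepeak chromatogram").
Stored m/z values are the literal values — self-description is preferred
over compression tricks such as delta-encoding, so files remain browsable
in standard tools (HDFView, h5dump, any HDF5 binding).  Chunked datasets
use gzip with the shuffle filter; the level is a write option.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import cv as _cv
from .cv import RoleAnnotation, TermCatalog, annotations_for_roles
from .model import (
    ChromatogramRecord,
    RunData,
    SpectrumRecord,
    build_scan_tree,
    compute_bpc,
    compute_tic,
    validate_run,
)

__all__ = [
    "FORMAT_VERSION",
    "StoreLayout",
    "StoreHandle",
    "AnnotationReport",
    "NotAStoreError",
    "StoreVersionError",
    "StoreIntegrityError",
    "write_ragged",
    "write_tree",
    "write_store",
    "open_store",
    "get_spectrum",
    "read_run",
    "read_chromatogram",
    "list_annotations",
]

FORMAT_VERSION = "1.0"

_ID_ATTR = "PSI-MS_ID"
_NAME_ATTR = "PSI-MS_NAME"

_PARENT_SENTINEL = -1  # integer datasets cannot hold null


class NotAStoreError(ValueError):
    """The HDF5 file was not written by this store (no format-version attribute)."""


class StoreVersionError(ValueError):
    """Format version or layout mode this reader does not understand."""


class StoreIntegrityError(ValueError):
    """Internally inconsistent file (e.g. ragged row counts disagree)."""


@dataclass(frozen=True)
class StoreLayout:
    """Write-time choices: layout mode, gzip level (0 = uncompressed chunks),
    and whether profile data is being exported (vs vendor centroids)."""

    mode: str = "ragged"  # "ragged" | "tree"
    compression_level: int = 4
    store_profile: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("ragged", "tree"):
            raise ValueError(f"unknown layout mode {self.mode!r}")
        if not 0 <= self.compression_level <= 9:
            raise ValueError("compression_level must be in 0..9")


@dataclass
class StoreHandle:
    """Lazy handle on a store file: layout, scan census and annotation map are
    read from metadata at open time; peak data only on demand."""

    path: str
    layout: StoreLayout
    n_spectra: int
    annotations: dict[str, RoleAnnotation]
    source_file: str = ""
    instrument_model: str = ""
    centroid_export: bool = True
    scan_index: dict[int, object] = field(default_factory=dict, repr=False)

    def get_spectrum(self, scan_number: int) -> SpectrumRecord:
        return get_spectrum(self, scan_number)

    def read_run(self) -> RunData:
        return read_run(self)


@dataclass
class AnnotationReport:
    """Outcome of an annotation-completeness walk over every dataset."""

    annotations: dict[str, RoleAnnotation]
    violations: list[str]

    @property
    def complete(self) -> bool:
        return not self.violations


# --------------------------------------------------------------------------
# writing

_VLEN_F8 = h5py.vlen_dtype(np.float64)
_STR = h5py.string_dtype(encoding="utf-8")


def _dataset_kwargs(layout: StoreLayout, length: int) -> dict:
    if length == 0:
        return {}
    kwargs: dict = {"chunks": True, "shuffle": True}
    if layout.compression_level > 0:
        kwargs.update(compression="gzip", compression_opts=layout.compression_level)
    return kwargs


def _annotate(dataset, ann: RoleAnnotation) -> None:
    dataset.attrs[_ID_ATTR] = ann.accession
    dataset.attrs[_NAME_ATTR] = ann.name
    dataset.attrs[ann.accession] = ann.name


def _require_new(path, overwrite: bool) -> None:
    if not overwrite and os.path.exists(path):
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")


def _check_valid(run: RunData) -> None:
    problems = validate_run(run)
    if problems:
        raise ValueError("invalid run: " + "; ".join(problems[:5]))


_RAGGED_ROLES = {
    "mz": "mz",
    "intensity": "intensity",
    "noise": "noise",
    "charge": "charge",
    "scan_number": "scan_number",
    "ms_level": "ms_level",
    "rt": "rt",
    "precursor_mz": "precursor_mz",
    "precursor_charge": "precursor_charge",
    "parent_scan": "parent_scan",
    "is_centroid": "is_centroid",
    "filter_string": "filter_string",
}


def _root_attrs(f: h5py.File, run: RunData, layout: StoreLayout,
                catalog: TermCatalog, n: int) -> None:
    f.attrs["format_version"] = FORMAT_VERSION
    f.attrs["layout_mode"] = layout.mode
    # booleans as int8: h5py's native bool is an HDF5 enum that generic
    # tooling (PyTables, rhdf5) cannot read
    f.attrs["store_profile"] = np.int8(layout.store_profile)
    f.attrs["source_file"] = run.source_file
    f.attrs["instrument_model"] = run.instrument_model
    f.attrs["centroid_export"] = np.int8(run.centroid_export)
    f.attrs["n_spectra"] = n
    f.attrs["cv_data_version"] = catalog.source_version


def _write_chromatograms(f: h5py.File, run: RunData, layout: StoreLayout,
                         anns: dict[str, RoleAnnotation]) -> None:
    for role, trace in (("bpc", compute_bpc(run)), ("tic", compute_tic(run))):
        n = len(trace)
        d = f.create_dataset(role, data=trace.value, dtype=np.float64,
                             **_dataset_kwargs(layout, n))
        _annotate(d, anns[role])
        d_rt = f.create_dataset(f"{role}_rt", data=trace.rt, dtype=np.float64,
                                **_dataset_kwargs(layout, n))
        _annotate(d_rt, anns["time"])


def write_ragged(run: RunData, path, layout: StoreLayout | None = None,
                 catalog: TermCatalog | None = None,
                 overwrite: bool = False) -> StoreHandle:
    """Write *run* in ragged-array layout and return an open handle.

    All annotations are resolved against *catalog* (bundled excerpt by
    default) before the file is created, so an annotation failure never
    leaves a partial file behind.
    """
    layout = layout or StoreLayout(mode="ragged")
    if layout.mode != "ragged":
        raise ValueError("write_ragged requires layout.mode == 'ragged'")
    catalog = catalog or _cv.load_bundled_catalog()
    _check_valid(run)
    anns = annotations_for_roles(
        catalog, list(_RAGGED_ROLES) + ["bpc", "tic", "time"]
    )
    _require_new(path, overwrite)

    n = len(run.spectra)
    has_noise = any(s.noise is not None for s in run.spectra)
    has_charge = any(s.charge is not None for s in run.spectra)

    with h5py.File(path, "w") as f:
        _root_attrs(f, run, layout, catalog, n)
        kw = _dataset_kwargs(layout, n)

        def ragged(name: str, rows) -> None:
            d = f.create_dataset(name, (n,), dtype=_VLEN_F8, **kw)
            for i, row in enumerate(rows):
                d[i] = row
            _annotate(d, anns[name])

        ragged("mz", (s.mz for s in run.spectra))
        ragged("intensity", (s.intensity for s in run.spectra))
        if has_noise:
            # scans without a noise estimate get an empty row: row count stays
            # uniform across all ragged datasets
            ragged("noise", (
                s.noise if s.noise is not None else np.empty(0)
                for s in run.spectra
            ))
        if has_charge:
            ragged("charge", (
                np.asarray(s.charge, dtype=np.float64)
                if s.charge is not None else np.empty(0)
                for s in run.spectra
            ))

        def fixed(name: str, data, dtype) -> None:
            d = f.create_dataset(name, data=np.asarray(data, dtype=dtype),
                                 dtype=dtype, **kw)
            _annotate(d, anns[name])

        fixed("scan_number", [s.scan_number for s in run.spectra], np.int64)
        fixed("ms_level", [s.ms_level for s in run.spectra], np.int32)
        fixed("rt", [s.retention_time for s in run.spectra], np.float64)
        fixed("precursor_mz",
              [np.nan if s.precursor_mz is None else s.precursor_mz
               for s in run.spectra], np.float64)
        fixed("precursor_charge",
              [s.precursor_charge for s in run.spectra], np.int32)
        fixed("parent_scan",
              [_PARENT_SENTINEL if s.precursor_scan is None else s.precursor_scan
               for s in run.spectra], np.int64)
        fixed("is_centroid", [int(s.is_centroid) for s in run.spectra], np.int8)

        d = f.create_dataset("filter_string",
                             data=[s.filter_string for s in run.spectra],
                             dtype=_STR, **kw)
        _annotate(d, anns["filter_string"])

        _write_chromatograms(f, run, layout, anns)

    return open_store(path)


def write_tree(run: RunData, path, layout: StoreLayout | None = None,
               catalog: TermCatalog | None = None,
               overwrite: bool = False) -> StoreHandle:
    """Write *run* in hierarchical scan-tree layout and return a handle.

    Scan groups are named ``scan_<zero-padded number>`` so lexicographic
    order equals scan order in any viewer; each product-ion scan's group is
    nested inside its parent acquisition's group.
    """
    layout = layout or StoreLayout(mode="tree")
    if layout.mode != "tree":
        raise ValueError("write_tree requires layout.mode == 'tree'")
    catalog = catalog or _cv.load_bundled_catalog()
    _check_valid(run)
    anns = annotations_for_roles(
        catalog, ["mz", "intensity", "noise", "charge", "bpc", "tic", "time"]
    )
    forest = build_scan_tree(run)
    _require_new(path, overwrite)

    by_scan = {s.scan_number: s for s in run.spectra}

    with h5py.File(path, "w") as f:
        _root_attrs(f, run, layout, catalog, len(run.spectra))
        scans_group = f.create_group("scans")

        def write_node(node, parent_group) -> None:
            s = by_scan[node.scan_number]
            g = parent_group.create_group(f"scan_{s.scan_number:06d}")
            g.attrs["scan_number"] = s.scan_number
            g.attrs["ms_level"] = s.ms_level
            g.attrs["rt"] = s.retention_time
            if s.precursor_mz is not None:
                g.attrs["precursor_mz"] = s.precursor_mz
            g.attrs["precursor_charge"] = s.precursor_charge
            g.attrs["parent_scan"] = (
                _PARENT_SENTINEL if s.precursor_scan is None else s.precursor_scan
            )
            g.attrs["filter_string"] = s.filter_string
            g.attrs["is_centroid"] = np.int8(s.is_centroid)
            kw = _dataset_kwargs(layout, s.n_peaks)
            for name, values in (("mz", s.mz), ("intensity", s.intensity)):
                d = g.create_dataset(name, data=values, dtype=np.float64, **kw)
                _annotate(d, anns[name])
            if s.noise is not None:
                d = g.create_dataset("noise", data=s.noise, dtype=np.float64, **kw)
                _annotate(d, anns["noise"])
            if s.charge is not None:
                d = g.create_dataset(
                    "charge", data=np.asarray(s.charge, dtype=np.float64),
                    dtype=np.float64, **kw)
                _annotate(d, anns["charge"])
            for child in node.children:
                write_node(child, g)

        for root in forest:
            write_node(root, scans_group)

        _write_chromatograms(f, run, layout, anns)

    return open_store(path)


def write_store(run: RunData, path, layout: StoreLayout | None = None,
                catalog: TermCatalog | None = None,
                overwrite: bool = False) -> StoreHandle:
    """Dispatch to :func:`write_ragged` or :func:`write_tree` by layout mode."""
    layout = layout or StoreLayout()
    writer = write_ragged if layout.mode == "ragged" else write_tree
    return writer(run, path, layout=layout, catalog=catalog, overwrite=overwrite)


# --------------------------------------------------------------------------
# reading


def _read_annotation(obj) -> RoleAnnotation | None:
    attrs = obj.attrs
    if _ID_ATTR not in attrs or _NAME_ATTR not in attrs:
        return None
    accession = str(attrs[_ID_ATTR])
    name = str(attrs[_NAME_ATTR])
    role = obj.name.rsplit("/", 1)[-1]
    fallback = _cv.ROLE_TABLE.get(role, ("", "", False))[2]
    return RoleAnnotation(role=role, accession=accession, name=name,
                          is_fallback=fallback)


def open_store(path) -> StoreHandle:
    """Open a store file lazily: metadata and attributes only, no peak data."""
    with h5py.File(path, "r") as f:
        if "format_version" not in f.attrs:
            raise NotAStoreError(f"{path}: no format-version attribute; "
                                 "not a recognized store")
        version = str(f.attrs["format_version"])
        if int(version.split(".")[0]) > int(FORMAT_VERSION.split(".")[0]):
            raise StoreVersionError(f"{path}: format version {version} is newer "
                                    f"than supported {FORMAT_VERSION}")
        mode = str(f.attrs["layout_mode"])
        if mode not in ("ragged", "tree"):
            raise StoreVersionError(f"{path}: unknown layout mode {mode!r}")
        layout = StoreLayout(mode=mode,
                             store_profile=bool(f.attrs.get("store_profile", True)))
        n_spectra = int(f.attrs.get("n_spectra", 0))

        annotations: dict[str, RoleAnnotation] = {}
        scan_index: dict[int, object] = {}

        def visit(name: str, obj) -> None:
            if isinstance(obj, h5py.Dataset):
                ann = _read_annotation(obj)
                if ann is not None:
                    annotations[name] = ann

        f.visititems(visit)

        if mode == "ragged":
            if "scan_number" in f:
                for i, sn in enumerate(f["scan_number"][...]):
                    scan_index[int(sn)] = i
        else:
            def visit_groups(name: str, obj) -> None:
                if isinstance(obj, h5py.Group) and "scan_number" in obj.attrs:
                    scan_index[int(obj.attrs["scan_number"])] = name

            if "scans" in f:
                f["scans"].visititems(visit_groups)

        handle = StoreHandle(
            path=os.fspath(path),
            layout=layout,
            n_spectra=n_spectra,
            annotations=annotations,
            source_file=str(f.attrs.get("source_file", "")),
            instrument_model=str(f.attrs.get("instrument_model", "")),
            centroid_export=bool(f.attrs.get("centroid_export", True)),
            scan_index=scan_index,
        )
    return handle


def _optional_row(values: np.ndarray, n_peaks: int) -> np.ndarray | None:
    # empty optional row with peaks present means "absent for this scan"
    if values.size == 0 and n_peaks > 0:
        return None
    if values.size == 0 and n_peaks == 0:
        return None
    return values


def _spectrum_from_ragged(f: h5py.File, i: int) -> SpectrumRecord:
    mz = np.asarray(f["mz"][i], dtype=np.float64)
    intensity = np.asarray(f["intensity"][i], dtype=np.float64)
    noise = _optional_row(np.asarray(f["noise"][i]), mz.size) if "noise" in f else None
    charge = None
    if "charge" in f:
        raw = _optional_row(np.asarray(f["charge"][i]), mz.size)
        charge = raw.astype(np.int32) if raw is not None else None
    pmz = float(f["precursor_mz"][i])
    parent = int(f["parent_scan"][i])
    fs = f["filter_string"][i]
    return SpectrumRecord(
        scan_number=int(f["scan_number"][i]),
        ms_level=int(f["ms_level"][i]),
        retention_time=float(f["rt"][i]),
        mz=mz,
        intensity=intensity,
        precursor_mz=None if np.isnan(pmz) else pmz,
        precursor_charge=int(f["precursor_charge"][i]),
        precursor_scan=None if parent == _PARENT_SENTINEL else parent,
        filter_string=fs.decode("utf-8") if isinstance(fs, bytes) else str(fs),
        is_centroid=bool(f["is_centroid"][i]),
        noise=noise,
        charge=charge,
    )


def _spectrum_from_group(g: h5py.Group) -> SpectrumRecord:
    a = g.attrs
    parent = int(a["parent_scan"])
    fs = a["filter_string"]
    return SpectrumRecord(
        scan_number=int(a["scan_number"]),
        ms_level=int(a["ms_level"]),
        retention_time=float(a["rt"]),
        mz=np.asarray(g["mz"][...], dtype=np.float64),
        intensity=np.asarray(g["intensity"][...], dtype=np.float64),
        precursor_mz=float(a["precursor_mz"]) if "precursor_mz" in a else None,
        precursor_charge=int(a["precursor_charge"]),
        precursor_scan=None if parent == _PARENT_SENTINEL else parent,
        filter_string=fs.decode("utf-8") if isinstance(fs, bytes) else str(fs),
        is_centroid=bool(a["is_centroid"]),
        noise=np.asarray(g["noise"][...], dtype=np.float64) if "noise" in g else None,
        charge=(np.asarray(g["charge"][...]).astype(np.int32)
                if "charge" in g else None),
    )


def get_spectrum(handle: StoreHandle, scan_number: int) -> SpectrumRecord:
    """Random access to one scan: only that scan's rows/groups are read."""
    if scan_number not in handle.scan_index:
        raise KeyError(f"scan {scan_number} not in store {handle.path}")
    loc = handle.scan_index[scan_number]
    with h5py.File(handle.path, "r") as f:
        if handle.layout.mode == "ragged":
            return _spectrum_from_ragged(f, int(loc))
        return _spectrum_from_group(f["scans"][str(loc)])


def read_run(handle: StoreHandle) -> RunData:
    """Reconstruct the full run; inverse of the writers for both layouts."""
    with h5py.File(handle.path, "r") as f:
        if handle.layout.mode == "ragged":
            lengths = {name: f[name].shape[0]
                       for name in ("mz", "intensity", "scan_number", "ms_level",
                                    "rt", "precursor_mz", "precursor_charge",
                                    "parent_scan", "is_centroid", "filter_string")
                       if name in f}
            if len(set(lengths.values())) > 1:
                raise StoreIntegrityError(
                    f"ragged datasets disagree on scan count: {lengths}")
            n = next(iter(lengths.values()), 0)
            if n != handle.n_spectra:
                raise StoreIntegrityError(
                    f"n_spectra attribute {handle.n_spectra} != dataset rows {n}")
            spectra = [_spectrum_from_ragged(f, i) for i in range(n)]
        else:
            spectra = [
                _spectrum_from_group(f["scans"][str(handle.scan_index[sn])])
                for sn in sorted(handle.scan_index)
            ]
    spectra.sort(key=lambda s: s.scan_number)
    return RunData(
        spectra=spectra,
        source_file=handle.source_file,
        instrument_model=handle.instrument_model,
        centroid_export=handle.centroid_export,
    )


def read_chromatogram(handle: StoreHandle, role: str) -> ChromatogramRecord:
    """Read a stored chromatogram ("bpc" or "tic") with its retention-time axis."""
    if role not in ("bpc", "tic"):
        raise KeyError(f"unknown chromatogram {role!r}")
    with h5py.File(handle.path, "r") as f:
        value = np.asarray(f[role][...], dtype=np.float64)
        rt = np.asarray(f[f"{role}_rt"][...], dtype=np.float64)
    return ChromatogramRecord(role=role, rt=rt, value=value,
                              annotation=handle.annotations.get(role))


def list_annotations(handle: StoreHandle) -> AnnotationReport:
    """Walk every dataset; report its CV annotation or flag it as violating.

    A dataset missing both ``PSI-MS_ID`` and ``PSI-MS_NAME`` is a
    completeness violation — reported, not raised.
    """
    annotations: dict[str, RoleAnnotation] = {}
    violations: list[str] = []
    with h5py.File(handle.path, "r") as f:
        def visit(name: str, obj) -> None:
            if not isinstance(obj, h5py.Dataset):
                return
            ann = _read_annotation(obj)
            if ann is None:
                violations.append(name)
            else:
                annotations[name] = ann

        f.visititems(visit)
    return AnnotationReport(annotations=annotations, violations=violations)
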