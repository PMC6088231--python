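"""HDF5 store: layouts, round trips, annotations, browsability guarantees."""

import os

import h5py
import numpy as np
import pytest

from mzhdf import (
    RunData,
    SpectrumRecord,
    StoreLayout,
    SynthParams,
    get_spectrum,
    list_annotations,
    open_store,
    read_chromatogram,
    read_run,
    synth_run,
    write_ragged,
    write_store,
    write_tree,
)
from mzhdf.store import NotAStoreError, StoreVersionError


@pytest.fixture()
def one_scan_run():
    return RunData(spectra=[SpectrumRecord(
        scan_number=1, ms_level=1, retention_time=0.0,
        mz=np.array([100.0, 200.0, 300.0]),
        intensity=np.array([1.0, 5.0, 3.0]),
    )])


class TestWriteRagged:
    def test_round_trip_is_bit_exact(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "r.h5")
        assert read_run(handle) == small_run

    def test_empty_run_file_still_fully_annotated(self, tmp_path):
        handle = write_ragged(RunData(), tmp_path / "empty.h5")
        assert handle.n_spectra == 0
        assert read_run(handle) == RunData()
        report = list_annotations(handle)
        assert report.complete and report.annotations  # datasets exist, length 0
        with h5py.File(handle.path) as f:
            assert f["mz"].shape == (0,)
            assert f["bpc"].shape == (0,)

    def test_bpc_dataset_carries_accession_named_attribute(self, one_scan_run,
                                                           tmp_path):
        handle = write_ragged(one_scan_run, tmp_path / "one.h5")
        with h5py.File(handle.path) as f:
            assert f["bpc"][...].tolist() == [5.0]
            assert f["bpc"].attrs["MS:1000628"] == "basepeak chromatogram"
            assert f["bpc"].attrs["PSI-MS_ID"] == "MS:1000628"
            assert f["bpc"].attrs["PSI-MS_NAME"] == "basepeak chromatogram"

    def test_refuses_to_overwrite_without_flag(self, one_scan_run, tmp_path):
        path = tmp_path / "once.h5"
        write_ragged(one_scan_run, path)
        with pytest.raises(FileExistsError):
            write_ragged(one_scan_run, path)
        write_ragged(one_scan_run, path, overwrite=True)  # explicit is fine

    def test_stored_values_are_literal_not_delta_encoded(self, small_run,
                                                         tmp_path):
        # a generic reader sees the m/z values themselves
        handle = write_ragged(small_run, tmp_path / "lit.h5")
        with h5py.File(handle.path) as f:
            for i, s in enumerate(small_run.spectra):
                assert np.array_equal(np.asarray(f["mz"][i]), s.mz)

    def test_spectral_datasets_are_64bit_floats(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "dtype.h5")
        with h5py.File(handle.path) as f:
            for name in ("mz", "intensity", "noise"):
                assert h5py.check_vlen_dtype(f[name].dtype) == np.float64
            for name in ("rt", "precursor_mz", "bpc", "bpc_rt", "tic", "tic_rt"):
                assert f[name].dtype == np.float64


class TestWriteTree:
    def test_nested_group_per_scan(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=1, peptides_per_ms1=1, seed=0))
        handle = write_tree(run, tmp_path / "t.h5")
        with h5py.File(handle.path) as f:
            g = f["scans/scan_000001/scan_000002"]
            assert "precursor_mz" in g.attrs
            assert g.attrs["ms_level"] == 2

    def test_ms1_only_run_has_flat_scan_groups(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=3, peptides_per_ms1=1, seed=1))
        ms1_only = RunData(spectra=[s for s in run if s.ms_level == 1],
                           source_file=run.source_file,
                           instrument_model=run.instrument_model,
                           centroid_export=run.centroid_export)
        handle = write_tree(ms1_only, tmp_path / "flat.h5")
        with h5py.File(handle.path) as f:
            names = list(f["scans"])
            assert names == sorted(names)
            for name in names:
                assert all(not isinstance(v, h5py.Group)
                           for v in f["scans"][name].values())

    def test_round_trip_and_cross_layout_equivalence(self, ms3_run, tmp_path):
        ragged = write_ragged(ms3_run, tmp_path / "r.h5")
        tree = write_tree(ms3_run, tmp_path / "t.h5")
        assert read_run(tree) == read_run(ragged) == ms3_run

    def test_every_scan_dataset_annotated_independently(self, ms3_run, tmp_path):
        handle = write_tree(ms3_run, tmp_path / "ann.h5")
        report = list_annotations(handle)
        assert report.complete
        mz_sets = [k for k in report.annotations if k.endswith("/mz")]
        assert len(mz_sets) == len(ms3_run)
        assert all(report.annotations[k].accession == "MS:1000514"
                   for k in mz_sets)


class TestOpenStore:
    def test_handle_exposes_layout_and_census(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "h.h5")
        reopened = open_store(handle.path)
        assert reopened.layout.mode == "ragged"
        assert reopened.n_spectra == len(small_run)
        assert reopened.annotations["bpc"].accession == "MS:1000628"

    def test_foreign_hdf5_file_rejected(self, tmp_path):
        path = tmp_path / "foreign.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("stuff", data=np.arange(3))
        with pytest.raises(NotAStoreError):
            open_store(path)

    def test_newer_major_version_refused(self, one_scan_run, tmp_path):
        path = tmp_path / "future.h5"
        write_ragged(one_scan_run, path)
        with h5py.File(path, "a") as f:
            f.attrs["format_version"] = "2.0"
        with pytest.raises(StoreVersionError):
            open_store(path)


class TestGetSpectrum:
    @pytest.mark.parametrize("writer", [write_ragged, write_tree],
                             ids=["ragged", "tree"])
    def test_single_scan_equals_source(self, small_run, tmp_path, writer):
        handle = writer(small_run, tmp_path / "s.h5")
        for sn in (1, 2, len(small_run)):
            assert get_spectrum(handle, sn) == small_run.scan(sn)

    def test_unknown_scan_is_lookup_error(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "s.h5")
        with pytest.raises(KeyError, match="99"):
            get_spectrum(handle, 99)

    def test_tree_ms3_precursor_chain_reaches_ms1_root(self, ms3_run, tmp_path):
        handle = write_tree(ms3_run, tmp_path / "t.h5")
        ms3_scan = next(s.scan_number for s in ms3_run if s.ms_level == 3)
        record = get_spectrum(handle, ms3_scan)
        hops = 0
        while record.precursor_scan is not None:
            record = get_spectrum(handle, record.precursor_scan)
            hops += 1
        assert record.ms_level == 1 and hops == 2


class TestAnnotationCompleteness:
    @pytest.mark.parametrize("writer", [write_ragged, write_tree],
                             ids=["ragged", "tree"])
    def test_fresh_store_has_zero_violations(self, small_run, tmp_path, writer):
        handle = writer(small_run, tmp_path / "a.h5")
        report = list_annotations(handle)
        assert report.violations == []

    def test_noise_maps_to_fallback_term(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "n.h5")
        ann = list_annotations(handle).annotations["noise"]
        assert (ann.accession, ann.name) == ("MS:1000513", "binary data array")
        assert ann.is_fallback

    def test_manually_stripped_dataset_is_reported(self, small_run, tmp_path):
        path = tmp_path / "strip.h5"
        write_ragged(small_run, path)
        with h5py.File(path, "a") as f:
            del f["mz"].attrs["PSI-MS_ID"]
            del f["mz"].attrs["PSI-MS_NAME"]
        report = list_annotations(open_store(path))
        assert report.violations == ["mz"]


class TestChromatogramStorage:
    def test_read_back_matches_recomputation(self, small_run, tmp_path):
        from mzhdf import compute_bpc, compute_tic
        handle = write_ragged(small_run, tmp_path / "c.h5")
        assert read_chromatogram(handle, "bpc") == compute_bpc(small_run)
        assert read_chromatogram(handle, "tic") == compute_tic(small_run)

    def test_unknown_role_rejected(self, small_run, tmp_path):
        handle = write_ragged(small_run, tmp_path / "c.h5")
        with pytest.raises(KeyError):
            read_chromatogram(handle, "xic")


class TestCompression:
    @pytest.mark.parametrize("mode", ["ragged", "tree"])
    def test_gzip6_no_larger_than_uncompressed_chunks(self, tmp_path, mode):
        run = synth_run(SynthParams(n_ms1=20, peptides_per_ms1=3, seed=11))
        assert len(run) >= 50
        paths = {}
        for level in (0, 6):
            p = tmp_path / f"{mode}{level}.h5"
            write_store(run, p, layout=StoreLayout(mode=mode,
                                                   compression_level=level))
            paths[level] = os.path.getsize(p)
        assert paths[6] <= paths[0]
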