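"""mzML reader/writer: round trips, dialects, and an external cross-reader."""

import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from mzhdf import (
    RunData,
    SpectrumRecord,
    SynthParams,
    WriteOptions,
    parse_mzml,
    synth_run,
    write_mzml,
)
from mzhdf.mzml import MzmlFormatError, MzmlWarning

MZML_NS = "http://psi.hupo.org/ms/mzml"


class TestRoundTrip:
    def test_empty_run(self, tmp_path):
        path = tmp_path / "empty.mzML"
        text = write_mzml(RunData(), path)
        assert 'count="0"' in text
        assert parse_mzml(str(path)) == RunData()

    def test_seed7_run_is_bit_exact_at_64bit(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=4, peptides_per_ms1=2, seed=7))
        path = tmp_path / "run.mzML"
        write_mzml(run, path)
        assert parse_mzml(str(path)) == run

    def test_ms3_run_keeps_precursor_chain(self, ms3_run, tmp_path):
        path = tmp_path / "ms3.mzML"
        write_mzml(ms3_run, path)
        back = parse_mzml(str(path))
        assert back == ms3_run
        ms3 = [s for s in back if s.ms_level == 3]
        assert ms3 and all(
            back.scan(s.precursor_scan).ms_level == 2 for s in ms3)

    def test_32bit_zlib_round_trip_within_float32_precision(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=3, seed=5))
        path = tmp_path / "run32.mzML"
        write_mzml(run, path, WriteOptions(precision=32, compression="zlib"))
        back = parse_mzml(str(path))
        for a, b in zip(run.spectra, back.spectra):
            assert np.allclose(a.mz, b.mz, rtol=1e-6)
            assert np.allclose(a.intensity, b.intensity, rtol=1e-6)
            # float32 round-trip is exactly the float32 cast
            assert np.array_equal(
                b.mz, a.mz.astype(np.float32).astype(np.float64))

    def test_indexed_wrapper_is_transparent(self, small_run, tmp_path):
        bare = tmp_path / "bare.mzML"
        wrapped = tmp_path / "indexed.mzML"
        write_mzml(small_run, bare)
        write_mzml(small_run, wrapped, WriteOptions(indexed=True))
        assert "indexedmzML" in wrapped.read_text()
        assert parse_mzml(str(wrapped)) == parse_mzml(str(bare)) == small_run

    def test_parsed_peak_count_equals_encoded_count(self, small_run, tmp_path):
        path = tmp_path / "run.mzML"
        write_mzml(small_run, path)
        back = parse_mzml(str(path))
        assert sum(s.n_peaks for s in back) == sum(s.n_peaks for s in small_run)


def _minimal_spectrum_xml(extra_arrays="", scan_cv="", spectrum_id="scan=1"):
    return textwrap.dedent(f"""\
        <mzML xmlns="{MZML_NS}" version="1.1.0">
          <run id="r">
            <spectrumList count="1">
              <spectrum index="0" id="{spectrum_id}" defaultArrayLength="2">
                <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
                <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
                <scanList count="1"><scan>{scan_cv}</scan></scanList>
                <binaryDataArrayList count="2">
                  <binaryDataArray>
                    <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
                    <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
                    <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
                    <binary>AAAAAAAAWUAAAAAAAABpQA==</binary>
                  </binaryDataArray>
                  <binaryDataArray>
                    <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
                    <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
                    <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
                    <binary>AAAAAAAA8D8AAAAAAAAAQA==</binary>
                  </binaryDataArray>
                  {extra_arrays}
                </binaryDataArrayList>
              </spectrum>
            </spectrumList>
          </run>
        </mzML>
        """)


class TestDialects:
    def test_noise_vector_via_non_standard_data_array(self):
        noise_array = f"""
            <binaryDataArray>
              <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
              <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
              <cvParam cvRef="MS" accession="MS:1000786" name="non-standard data array" value="noise"/>
              <binary>AAAAAAAA4D8AAAAAAADgPw==</binary>
            </binaryDataArray>"""
        run = parse_mzml(_minimal_spectrum_xml(extra_arrays=noise_array))
        s = run.spectra[0]
        assert s.mz.tolist() == [100.0, 200.0]
        assert s.noise is not None and s.noise.tolist() == [0.5, 0.5]

    def test_unknown_array_accession_preserved_as_other(self):
        other = f"""
            <binaryDataArray>
              <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
              <cvParam cvRef="MS" accession="MS:1000617" name="wavelength array" value=""/>
              <binary>AAAAAAAA4D8AAAAAAADgPw==</binary>
            </binaryDataArray>"""
        run = parse_mzml(_minimal_spectrum_xml(extra_arrays=other))
        assert "MS:1000617" in run.spectra[0].other_arrays

    def test_seconds_unit_converted_to_minutes(self):
        scan_cv = ('<cvParam cvRef="MS" accession="MS:1000016" '
                   'name="scan start time" value="90" unitName="second"/>')
        run = parse_mzml(_minimal_spectrum_xml(scan_cv=scan_cv))
        assert run.spectra[0].retention_time == pytest.approx(1.5)

    def test_missing_unit_warns_and_assumes_minutes(self):
        scan_cv = ('<cvParam cvRef="MS" accession="MS:1000016" '
                   'name="scan start time" value="2.5"/>')
        with pytest.warns(MzmlWarning, match="assuming minutes"):
            run = parse_mzml(_minimal_spectrum_xml(scan_cv=scan_cv))
        assert run.spectra[0].retention_time == 2.5

    def test_scan_number_falls_back_to_ordinal(self):
        run = parse_mzml(_minimal_spectrum_xml(spectrum_id="noTokenHere"))
        assert run.spectra[0].scan_number == 1

    def test_missing_intensity_array_is_format_error(self):
        xml = _minimal_spectrum_xml().replace(
            'accession="MS:1000515" name="intensity array"',
            'accession="MS:1000617" name="wavelength array"')
        with pytest.raises(MzmlFormatError, match="scan=1"):
            parse_mzml(xml)

    def test_multiple_precursors_first_wins_with_warning(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=1, peptides_per_ms1=1, seed=1))
        text = write_mzml(run)
        ms2 = run.spectra[1]
        # duplicate the precursor element wholesale
        text = text.replace('<precursorList count="1">',
                            '<precursorList count="2">')
        start = text.index("<precursor ")
        end = text.index("</precursor>") + len("</precursor>")
        block = text[start:end]
        text = text[:end] + block + text[end:]
        with pytest.warns(MzmlWarning, match="keeping the first"):
            back = parse_mzml(text)
        assert back.scan(ms2.scan_number).precursor_mz == ms2.precursor_mz


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="needs Rscript")
class TestExternalCrossReader:
    """mzR (Bioconductor) as an independent reader of our mzML output."""

    def test_mzr_reads_identical_peaks_and_metadata(self, tmp_path):
        run = synth_run(SynthParams(n_ms1=2, peptides_per_ms1=2, seed=3))
        path = tmp_path / "run.mzML"
        write_mzml(run, path)
        script = tmp_path / "read.R"
        script.write_text(textwrap.dedent(f"""\
            suppressMessages(library(mzR))
            f <- openMSfile("{path}")
            h <- header(f)
            cat("NSPEC", nrow(h), "\\n")
            for (i in seq_len(nrow(h))) {{
              p <- peaks(f, i)
              cat("SCAN", h$acquisitionNum[i], h$msLevel[i], nrow(p), "\\n")
              cat(sprintf("MZ %.17g\\n", p[, 1]), sep = "")
              cat(sprintf("INT %.17g\\n", p[, 2]), sep = "")
            }}
            """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True).stdout.splitlines()
        assert out[0].split() == ["NSPEC", str(len(run))]
        scans: dict[int, dict] = {}
        current = None
        for line in out[1:]:
            tag, *rest = line.split()
            if tag == "SCAN":
                sn, level, npeaks = map(int, rest)
                current = scans[sn] = {"level": level, "n": npeaks,
                                       "mz": [], "int": []}
            elif tag == "MZ":
                current["mz"].append(float(rest[0]))
            elif tag == "INT":
                current["int"].append(float(rest[0]))
        for s in run.spectra:
            got = scans[s.scan_number]
            assert got["level"] == s.ms_level
            assert got["n"] == s.n_peaks
            assert np.array_equal(np.array(got["mz"]), s.mz)
            assert np.array_equal(np.array(got["int"]), s.intensity)
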