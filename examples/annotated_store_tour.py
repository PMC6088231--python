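"""What a generic HDF5 consumer sees inside a store.

Writes a small run, then walks the file with h5py alone — no knowledge of
this package's reader — printing each dataset with the PSI-MS controlled-
vocabulary attributes that make the file self-describing.  This is the
programmatic version of opening the file in HDFView.
"""

import tempfile

import h5py

from mzhdf import SynthParams, synth_run, to_peaklist_json, write_ragged

run = synth_run(SynthParams(n_ms1=3, peptides_per_ms1=1, seed=1))

with tempfile.TemporaryDirectory() as tmp:
    handle = write_ragged(run, f"{tmp}/store.h5")
    with h5py.File(handle.path) as f:
        print(f"layout={f.attrs['layout_mode']}  scans={f.attrs['n_spectra']}")
        for name in sorted(f):
            d = f[name]
            acc = d.attrs["PSI-MS_ID"]
            term = d.attrs["PSI-MS_NAME"]
            print(f"  /{name:<18} {str(d.shape):<8} {acc} \"{term}\"")

scan2 = run.scan(2)
print()
print(f"scan 2 (MS{scan2.ms_level}, precursor {scan2.precursor_mz:.2f} m/z) "
      "as viewer JSON:")
print(to_peaklist_json(scan2)[:76] + " ...")
print("Any dataset above is readable by any HDF5 tool; the MS:xxxxxxx")
print("attributes say what each one means, no external schema needed.")
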