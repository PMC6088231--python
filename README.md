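# mzhdf

Self-describing HDF5 storage for mass-spectrometry runs, annotated with the
PSI-MS controlled vocabulary.

Mass spectrometers write proprietary binary files; the community exchange
format, mzML, wraps the numeric payload in XML with peak vectors hidden in
base64 blobs — sizes inflate and every consumer needs special-purpose
decoding. `mzhdf` is a converter and library for the alternative: store the
run in plain ("vanilla") HDF5, where a generic viewer or any language's
HDF5 binding can see — and read — every peak directly, and let the PSI-MS
controlled vocabulary say what each dataset means.

Concretely, a store holds either ragged per-element arrays (`mz`,
`intensity`, `noise`, `charge`: one variable-length float64 row per scan)
or one group per scan nested by MSⁿ precursor lineage, plus per-scan
metadata and the derived chromatograms. Every dataset carries its CV term
twice over: `PSI-MS_ID`/`PSI-MS_NAME` attributes, and an attribute keyed by
the accession itself — the `bpc` dataset has an attribute `MS:1000628` with
value `"basepeak chromatogram"`. Where PSI-MS has no specific term (the
vendor per-centroid noise array), the store falls back on the parent term
`MS:1000513` "binary data array". Values are stored literally — no delta
encoding, doubles wherever possible — trading a little compression for
files any HDF5 tool can browse.

The package is aimed at proteomics/metabolomics tool builders and
pipeline authors who need fast random access to scans, cross-language
(Python/R/viewer) access to the same file, or a self-contained testbed:
a deterministic synthetic LC-MS/MS generator (peptide b/y fragment
spectra, noise and charge arrays, MS3 scan trees) makes the whole system
testable without a single vendor file.

## The arithmetic at the core

For a peptide of residues $r_1 \dots r_n$, the neutral monoisotopic mass is
$M = \sum_i m(r_i) + m_{\mathrm{H_2O}}$, an ion's m/z is
$(M + z\,m_p)/z$, and the singly charged fragment series are
$b_i = \sum_{j\le i} m(r_j) + m_p$ and
$y_i = \sum_{j>n-i} m(r_j) + m_{\mathrm{H_2O}} + m_p$.
The basepeak chromatogram (MS:1000628) is the per-scan intensity maximum
against retention time; the total ion current chromatogram (MS:1000235) is
the per-scan sum.

## Worked example

```bash
$ python examples/worked_spectrum.py
peptide                DALSSVQESQVAQQAR
monoisotopic mass      1715.8438 Da
[M+2H]2+ m/z           858.9292  (instrument-reported: 858.92)
b2, b3                 187.0713, 300.1554
y1, y2                 175.1190, 246.1561
```

DALSSVQESQVAQQAR (bovine apolipoprotein C-III) is the reference spectrum:
the theoretical doubly protonated m/z, 858.9292, agrees with the
instrument-reported 858.92 to ~0.01 Th, and the b/y values are what a
search engine would predict for its MS/MS spectrum.

The full pipeline on a synthetic run:

```bash
$ python examples/synthetic_roundtrip.py
synthetic run: 50 scans (10 MS1, 20 MS2, 20 MS3)
mzML round trip   identical=True  (147 KiB)
ragged layout     identical=True  (84 KiB, 16 annotated datasets)
tree   layout     identical=True  (589 KiB, 184 annotated datasets)
basepeak chromatogram: 10 points, apex 1429596 at 8.00 min [MS:1000628 basepeak chromatogram]
```

`identical=True` means bit-exact: every float array survives
mzML → parse → HDF5 → read unchanged. `examples/annotated_store_tour.py`
walks a store with raw h5py and prints each dataset with its CV term.

## Command line

```bash
mzhdf synth run --seed 42 --n-ms1 10        # synthetic run.mzML + run.h5
mzhdf convert run.mzML run_tree.h5 --layout tree
mzhdf inspect run.h5                         # inventory + CV annotations
mzhdf extract run.h5 --scan 2                # viewer-ready JSON peak list
mzhdf extract run.h5 --chromatogram bpc
```

From R, `r/read_store.R` reads the same files (see `r/store_tour.Rmd`);
the extracted arrays are bit-identical to the Python reader's.

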