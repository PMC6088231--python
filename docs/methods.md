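# Methods

## The format

`mzhdf` stores an LC-MS/MS run in plain HDF5 with two design rules: every
stored value is the literal measured value (64-bit IEEE floats, no delta
encoding, no custom packing), and every dataset carries the PSI-MS
controlled-vocabulary (CV) term that defines its meaning. A file is
therefore fully interpretable by any generic HDF5 consumer — HDFView,
h5dump, PyTables, rhdf5 — with no schema knowledge beyond HDF5 itself.

Two layouts cover the two natural shapes of MS data:

- **ragged** (default): one variable-length (vlen) float64 dataset per
  element type (`mz`, `intensity`, and, when the acquisition provides them,
  `noise` and per-centroid `charge`), one row per scan, plus fixed-length
  per-scan metadata datasets (`scan_number`, `ms_level`, `rt`,
  `precursor_mz`, `precursor_charge`, `parent_scan`, `is_centroid`,
  `filter_string`). Row *i* of every dataset describes scan *i*; any single
  scan is one row read.
- **tree**: one group per scan, named `scan_<6-digit zero-padded number>`
  (so lexicographic order equals scan order in a viewer) and nested under
  the group of the scan that selected its precursor. MSⁿ scan trees become
  literal group hierarchies, and every individual dataset can be annotated
  independently.

Both layouts store the derived chromatograms at the root as paired
datasets `bpc`/`bpc_rt` and `tic`/`tic_rt` (value and retention-time axis),
since a chromatogram without its axis is not self-contained.

### CV annotation

Annotations are written in two redundant conventions, because both are
useful to generic viewers: attribute pair `PSI-MS_ID`/`PSI-MS_NAME`, and a
single attribute whose *key* is the accession and whose value is the term
name (the `bpc` dataset carries `MS:1000628` = "basepeak chromatogram").
The role→term table is hard-coded and verified against a parsed OBO
catalog at write time; a name mismatch aborts the write before the file is
created. Roles for which PSI-MS defines no specific term — the vendor
per-centroid noise estimate, scan bookkeeping integers — fall back on the
parent term "binary data array" (MS:1000513) and are flagged
`is_fallback`. Per-centroid charge uses the official "charge array"
(MS:1000516). The package bundles a ~30-term excerpt of the PSI-MS
ontology so everything works offline; a full `psi-ms.obo` can be supplied
to the CLI, and the catalog records its `data-version` in the file.

### Numerical and encoding choices

- All spectral and chromatogram floats are stored as little-endian float64;
  per-centroid charge is integral and stored as float64 rows (ragged, so
  vlen dtypes stay uniform) or float64 datasets (tree) and surfaces as
  int32 in memory. Booleans are stored as int8 because h5py's native bool
  is an HDF5 enum that several generic readers cannot interpret.
- `parent_scan` uses −1 as the "no parent" sentinel; `precursor_mz` uses
  NaN. A scan whose optional noise/charge vector is absent gets an empty
  vlen row, keeping row counts uniform; an empty optional row reads back
  as "absent".
- Chunked datasets use gzip (default level 4) with the shuffle filter;
  level 0 means chunked but unfiltered. HDF5 applies filters only to the
  vlen *references*, not the heap data itself — an accepted cost of
  keeping per-scan rows directly browsable; the qualitative size guarantee
  (level 6 ≤ level 0) still holds and is tested on runs of ≥ 50 scans.
- The TIC is accumulated left-to-right over stored peak order, making the
  "exactly equals a brute-force pass" contract well-defined independent of
  array-library summation strategy (pairwise summation differs in the last
  ulp). The BPC is a plain maximum; empty peak lists contribute 0 so
  traces stay aligned with scan indices. Both default to MS1 scans, with
  the level as a parameter.
- Retention time is minutes everywhere in the API and the store; the mzML
  reader converts a declared seconds unit and warns (assuming minutes)
  when no unit is declared.

### mzML path

The importer reads mzML 1.1, bare or in the `indexedmzML` wrapper (the
index is skipped — the store provides its own random access). Binary data
arrays are decoded from base64-wrapped little-endian 32/64-bit floats,
optionally zlib-compressed; MS-Numpress is deliberately unsupported.
Arrays map to roles by CV accession (MS:1000514 m/z, MS:1000515 intensity,
MS:1000516 charge, MS:1000786 "non-standard data array" named `noise` for
the noise vector); unrecognized array accessions are preserved as `other`
arrays in memory. Scan numbers come from the `scan=` token of the
spectrum id, falling back to 1-based ordinals; the first precursor wins
when a spectrum lists several (with a warning). The companion writer
emits a minimal schema-shaped document — enough for fixtures and round
trips, verified bit-exact at 64-bit/uncompressed and against Bioconductor
`mzR` as an independent reader; full metadata chains are out of scope.
No vendor RAW reading: open formats plus the synthetic generator replace
proprietary ingestion.

## The synthetic generator

The generator emulates the *structure* of a data-dependent acquisition,
not instrument physics: `n_ms1` survey scans evenly spaced over `rt_span`
minutes (defaults 10 scans / 10 min), each followed by `peptides_per_ms1`
(default 2) MS2 scans of doubly charged tryptic-peptide precursors drawn
from a pool of six real sequences, optionally each followed by an MS3 of
the peptide's longest y-ion. Every product scan immediately follows and
references its parent, so scan trees are non-trivial and flattening the
tree reproduces scan order.

- MS1 content: each pool peptide appears at its 2+ m/z, rendered either as
  a 5-point Gaussian stencil in m/z (profile mode, default) or a single
  centroid; amplitudes follow a Gaussian elution profile (σ = 15 % of the
  run span) so the BPC has shape.
- MS2/MS3 content: the full singly charged b/y series with log-normal
  intensities (σ = 0.5, base peak scaled to 10⁴) — arbitrary but fixed;
  nothing downstream depends on the distribution. Each centroid gets a
  noise value `uniform(0.5, 2.0)·√intensity`, mimicking vendor noise
  arrays structurally, and a unit charge estimate.
- `noise_sd` (default 0.3) is a log-normal multiplicative jitter on
  intensities; `seed` drives a `numpy` `SeedSequence` per scan, so equal
  seeds give byte-identical runs and the mzML writer's output is
  byte-stable.

Mass arithmetic is monoisotopic throughout (residue-table sum + water;
ions add one proton mass per charge), with no modifications — matching how
the reference spectrum (DALSSVQESQVAQQAR, [M+2H]²⁺ ≈ 858.93 vs the
instrument-reported 858.92) is computed. The test suite checks the table
against an independent element-composition oracle (residue formulas ×
isotopic element masses) to 10⁻⁴ Da and against `pyteomics.mass`.

What passing tests on synthetic runs do **not** show: correctness on real
files with isotope envelopes, multiplexed precursors, ion-mobility or
SRM/chromatogram-centric layouts, or vendor metadata beyond the modeled
fields — the generator never produces those, and the mzML reader
deliberately models only the fields in `SpectrumRecord`.

## Cross-language access

The R reader (`r/read_store.R` plus a knitr vignette) is deliberately
thin and read-only: chromatograms, per-scan metadata and tree-mode scan
groups are read natively with `rhdf5`; ragged-mode peak rows are HDF5
vlen datasets, which `rhdf5` (≤ 2.46) does not implement, so single rows
are extracted via `h5dump -m "%.17g"` — 17 significant digits round-trip
IEEE doubles exactly, and the test suite asserts bit-identity between the
R-side and Python-side arrays on both layouts.

## Problem sizes

Round-trip and acceptance checks run on 50-survey-scan runs (150 scans,
~4,500 peaks); the chromatogram oracle uses 20 independent 15-scan runs;
codec identity uses 1,000 random vectors across all precision ×
compression combinations; size monotonicity uses ≥ 50-scan runs, where
fixed-dataset compression dominates chunk overhead. These sizes exercise
every code path (MS1/MS2/MS3, profile and centroid, empty rows) while
keeping the whole suite interactive.

## Known limitations

- One precursor per spectrum; no SRM, no ion mobility, no imaging.
- No append/edit of existing stores; a store is written in one pass.
- `list_annotations` checks attribute presence and accession/name pairs,
  not deep ontology consistency (a wrong-but-well-formed accession written
  by a third party would pass the completeness walk).
- The bundled OBO excerpt contains only the terms the store uses;
  `has_ancestor` queries outside it require loading the full PSI-MS file.
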