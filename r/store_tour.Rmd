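---
title: "Reading an mzhdf store from R"
output: html_document
---

The HDF5 stores written by the Python package are plain ("vanilla") HDF5:
no delta encoding, 64-bit float datasets with self-explanatory names, and a
PSI-MS controlled-vocabulary attribute on every dataset. That makes them
readable from R with nothing but generic HDF5 tooling — this vignette pulls
out the basepeak chromatogram and one MS/MS spectrum and plots both.

Generate a fixture first (any store works):

```bash
mzhdf synth run --seed 42 --n-ms1 10
```

```{r setup, message=FALSE}
source("read_store.R")   # rhdf5 + h5dump helpers
path <- "run.h5"
```

The root attributes say what the file is:

```{r attrs}
h5readAttributes(path, "/")[c("format_version", "layout_mode", "n_spectra")]
```

## Basepeak chromatogram

`bpc` and its retention-time axis `bpc_rt` are ordinary float64 datasets;
the `MS:1000628` attribute identifies the trace.

```{r bpc, fig.height=3.5}
bpc <- read_bpc(path)
plot(bpc$rt, bpc$value, type = "l", xlab = "retention time [min]",
     ylab = "basepeak intensity", main = "basepeak chromatogram (MS:1000628)")
```

## One spectrum

`read_spectrum` resolves a scan number in either layout: tree-mode scan
groups are read natively with `rhdf5`; ragged-mode peak rows are HDF5
variable-length datasets, which `rhdf5` cannot read yet, so they are
extracted through `h5dump -m "%.17g"` (17 significant digits round-trip an
IEEE double exactly — the values are bit-identical to what Python sees).

```{r spectrum, fig.height=3.5}
sp <- read_spectrum(path, 2)
plot(sp$mz, sp$intensity, type = "h", xlab = "m/z", ylab = "intensity",
     main = sprintf("scan 2: MS%d, precursor %.2f m/z",
                    sp$ms_level, sp$precursor_mz))
```

Nothing above knows anything about the writing package — the file explains
itself, which is the point of the format.
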