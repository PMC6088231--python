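# Minimal R reader for mzhdf HDF5 stores.
#
# Demonstrates that the format is language-neutral: the basepeak chromatogram
# and any single spectrum can be pulled out of a store with generic HDF5
# tooling, no Python required.
#
# Fixed-length datasets (bpc/tic, per-scan metadata) and tree-layout scan
# groups are read natively with rhdf5.  Ragged-layout peak rows live in HDF5
# variable-length (VLEN) datasets, which rhdf5 (<= 2.46) cannot read; those
# rows are extracted through `h5dump -m "%.17g"`, whose 17-significant-digit
# ASCII output round-trips IEEE doubles exactly.
#
# Usage as a script (prints arrays at full precision, one value per line):
#   Rscript read_store.R dump <store.h5> <scan_number>

suppressMessages(library(rhdf5))

.root_attr <- function(path, name) {
  a <- h5readAttributes(path, "/")
  as.character(a[[name]])
}

read_bpc <- function(path) {
  list(rt = as.numeric(h5read(path, "bpc_rt")),
       value = as.numeric(h5read(path, "bpc")))
}

# Parse one row of an HDF5 VLEN float dataset via h5dump full-precision ASCII.
.vlen_row <- function(path, dataset, row_index0) {
  out <- system2("h5dump",
                 c("-d", dataset, "-s", row_index0, "-c", "1", "-y",
                   "-m", "%.17g", path),
                 stdout = TRUE)
  start <- grep("DATA \\{", out)[1]
  closers <- grep("^\\s*\\}", out)
  end <- closers[closers > start][1]
  body <- paste(out[(start + 1):(end - 1)], collapse = " ")
  body <- gsub("[(){}]", " ", body)
  vals <- strsplit(body, ",")[[1]]
  vals <- vals[grepl("[0-9]", vals)]
  as.numeric(vals)
}

.tree_scan_group <- function(path, scan_number) {
  listing <- h5ls(path, recursive = TRUE)
  wanted <- sprintf("scan_%06d", scan_number)
  hit <- listing[listing$otype == "H5I_GROUP" & listing$name == wanted, ]
  if (nrow(hit) == 0) stop(sprintf("scan %d not in store", scan_number))
  paste0(sub("^/$", "", hit$group[1]), "/", hit$name[1])
}

read_spectrum <- function(path, scan_number) {
  mode <- .root_attr(path, "layout_mode")
  if (mode == "ragged") {
    scans <- as.integer(h5read(path, "scan_number"))
    i <- match(scan_number, scans)
    if (is.na(i)) stop(sprintf("scan %d not in store", scan_number))
    mz <- .vlen_row(path, "/mz", i - 1)
    intensity <- .vlen_row(path, "/intensity", i - 1)
    list(scan_number = scan_number,
         ms_level = as.integer(h5read(path, "ms_level"))[i],
         precursor_mz = as.numeric(h5read(path, "precursor_mz"))[i],
         mz = mz, intensity = intensity)
  } else if (mode == "tree") {
    g <- .tree_scan_group(path, scan_number)
    a <- h5readAttributes(path, g)
    list(scan_number = scan_number,
         ms_level = as.integer(a$ms_level),
         precursor_mz = if (is.null(a$precursor_mz)) NA_real_
                        else as.numeric(a$precursor_mz),
         mz = as.numeric(h5read(path, paste0(g, "/mz"))),
         intensity = as.numeric(h5read(path, paste0(g, "/intensity"))))
  } else {
    stop(sprintf("unknown layout mode '%s'", mode))
  }
}

# script entry point: full-precision dump for cross-language comparison
if (sys.nframe() == 0 && !interactive()) {
  args <- commandArgs(trailingOnly = TRUE)
  if (length(args) >= 1 && args[1] == "dump") {
    path <- args[2]
    scan <- as.integer(args[3])
    bpc <- read_bpc(path)
    sp <- read_spectrum(path, scan)
    emit <- function(tag, v) cat(sprintf("%s %s\n", tag, sprintf("%.17g", v)),
                                 sep = "")
    emit("BPC_RT", bpc$rt)
    emit("BPC_VALUE", bpc$value)
    emit("MZ", sp$mz)
    emit("INTENSITY", sp$intensity)
    cat(sprintf("MS_LEVEL %d\n", sp$ms_level))
    cat(sprintf("PRECURSOR_MZ %.17g\n", sp$precursor_mz))
  }
}
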