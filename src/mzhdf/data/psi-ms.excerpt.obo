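format-version: 1.2
data-version: 4.1.95-excerpt
ontology: ms
remark: Hand-transcribed excerpt of the PSI-MS controlled vocabulary containing only
remark: the terms this package's HDF5 store and mzML codec reference. Accessions and
remark: names follow the published psi-ms.obo; is_a links outside this excerpt are
remark: omitted. Not the full ontology.

[Term]
id: MS:1000294
name: mass spectrum

[Term]
id: MS:1000579
name: MS1 spectrum
is_a: MS:1000294 ! mass spectrum

[Term]
id: MS:1000580
name: MSn spectrum
is_a: MS:1000294 ! mass spectrum

[Term]
id: MS:1000525
name: spectrum representation

[Term]
id: MS:1000127
name: centroid spectrum
is_a: MS:1000525 ! spectrum representation

[Term]
id: MS:1000128
name: profile spectrum
is_a: MS:1000525 ! spectrum representation

[Term]
id: MS:1000503
name: scan attribute

[Term]
id: MS:1000511
name: ms level
is_a: MS:1000503 ! scan attribute

[Term]
id: MS:1000016
name: scan start time
is_a: MS:1000503 ! scan attribute

[Term]
id: MS:1000512
name: filter string
is_a: MS:1000503 ! scan attribute

[Term]
id: MS:1000455
name: ion selection attribute

[Term]
id: MS:1000744
name: selected ion m/z
is_a: MS:1000455 ! ion selection attribute

[Term]
id: MS:1000041
name: charge state
is_a: MS:1000455 ! ion selection attribute

[Term]
id: MS:1000513
name: binary data array

[Term]
id: MS:1000514
name: m/z array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000515
name: intensity array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000516
name: charge array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000517
name: signal to noise array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000595
name: time array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000786
name: non-standard data array
is_a: MS:1000513 ! binary data array

[Term]
id: MS:1000810
name: mass chromatogram

[Term]
id: MS:1000628
name: basepeak chromatogram
is_a: MS:1000810 ! mass chromatogram

[Term]
id: MS:1000235
name: total ion current chromatogram
is_a: MS:1000810 ! mass chromatogram

[Term]
id: MS:1000518
name: binary data type

[Term]
id: MS:1000521
name: 32-bit float
is_a: MS:1000518 ! binary data type

[Term]
id: MS:1000523
name: 64-bit float
is_a: MS:1000518 ! binary data type

[Term]
id: MS:1000572
name: binary data compression type

[Term]
id: MS:1000574
name: zlib compression
is_a: MS:1000572 ! binary data compression type

[Term]
id: MS:1000576
name: no compression
is_a: MS:1000572 ! binary data compression type

[Term]
id: MS:1000031
name: instrument model

[Term]
id: MS:1000030
name: vendor
is_obsolete: true
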