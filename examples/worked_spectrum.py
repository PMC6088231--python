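"""Peptide mass arithmetic for the package's reference spectrum.

DALSSVQESQVAQQAR is a tryptic peptide of bovine apolipoprotein C-III; its
doubly charged ion is the worked example every part of this package can be
checked against.  The script computes the neutral monoisotopic mass, the
[M+2H]2+ m/z an Orbitrap would report, and the first few b/y fragment ions
an MS/MS spectrum of it would contain.
"""

from mzhdf import fragment_mzs, peptide_monoisotopic_mass, precursor_mz

PEPTIDE = "DALSSVQESQVAQQAR"

mass = peptide_monoisotopic_mass(PEPTIDE)
mz2 = precursor_mz(PEPTIDE, 2)
b, y = fragment_mzs(PEPTIDE)

print(f"peptide                {PEPTIDE}")
print(f"monoisotopic mass      {mass:.4f} Da")
print(f"[M+2H]2+ m/z           {mz2:.4f}  (instrument-reported: 858.92)")
print(f"b2, b3                 {b[1]:.4f}, {b[2]:.4f}")
print(f"y1, y2                 {y[0]:.4f}, {y[1]:.4f}")
print()
print("The m/z values are what a search engine would predict for this")
print("sequence; the 2+ precursor agrees with the instrument to ~0.01 Th.")
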