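"""Synthetic LC-MS/MS run generation.

Everything downstream of acquisition — mzML round trips, HDF5 layouts,
chromatograms, viewers — is testable on runs generated here, without any
vendor file.  The generator emulates a data-dependent acquisition: evenly
spaced MS1 survey scans over a retention-time span, each followed by MS/MS
scans of peptide precursors drawn from a sequence pool (optionally with an
MS3 stage fragmenting the strongest y-ion).  Fragment spectra carry the b/y
ion series with log-normal intensities, a per-centroid noise vector and a
per-centroid charge vector, as vendor centroid streams do.

The peptide mass arithmetic is monoisotopic throughout: a peptide's neutral
mass is the sum of its residue masses plus one water; an ion's m/z is
``(M + z·m_proton) / z``.  The default sequence pool includes
DALSSVQESQVAQQAR (bovine apolipoprotein C-III), whose doubly charged ion at
m/z 858.93 is this package's worked reference spectrum.

What the generator does *not* emulate: isotope envelopes, realistic elution
peak shapes, co-isolation, or missed cleavages — structure, not
instrument physics, is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import RunData, SpectrumRecord

__all__ = [
    "ResidueMassTable",
    "STANDARD_TABLE",
    "SynthParams",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "fragment_mzs",
    "synth_msms_spectrum",
    "synth_run",
]

# Monoisotopic residue masses (Da), standard 20 amino acids; residue = amino
# acid minus water. Water/proton constants from CODATA/IUPAC isotopic masses.
_RESIDUES = {
    "G": 57.02146372,
    "A": 71.03711378,
    "S": 87.03202840,
    "P": 97.05276384,
    "V": 99.06841390,
    "T": 101.04767846,
    "C": 103.00918447,
    "L": 113.08406396,
    "I": 113.08406396,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857750,
    "K": 128.09496300,
    "E": 129.04259308,
    "M": 131.04048459,
    "H": 137.05891186,
    "F": 147.06841390,
    "R": 156.10111102,
    "Y": 163.06332852,
    "W": 186.07931294,
}

WATER_MONO = 18.01056468403
PROTON_MASS = 1.00727646688


@dataclass(frozen=True)
class ResidueMassTable:
    """One-letter residue code -> monoisotopic residue mass, plus constants."""

    residues: dict[str, float] = field(default_factory=lambda: dict(_RESIDUES))
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON_MASS

    def mass(self, code: str) -> float:
        try:
            return self.residues[code]
        except KeyError:
            raise ValueError(f"unknown residue code {code!r}") from None


STANDARD_TABLE = ResidueMassTable()

DEFAULT_POOL = (
    "DALSSVQESQVAQQAR",  # bovine apolipoprotein C-III tryptic peptide
    "LVNEVTEFAK",        # serum albumin
    "YLYEIAR",
    "AEFVEVTK",
    "HLVDEPQNLIK",
    "GITWGEETLMEYLENPK",
)


def peptide_monoisotopic_mass(
    sequence: str, table: ResidueMassTable = STANDARD_TABLE
) -> float:
    """Neutral monoisotopic mass: sum of residue masses plus one water."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    return sum(table.mass(c) for c in sequence) + table.water_mass


def precursor_mz(
    sequence: str, charge: int, table: ResidueMassTable = STANDARD_TABLE
) -> float:
    """m/z of the ``[M + z·H]^z+`` ion: ``(M + z·m_proton) / z``."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    m = peptide_monoisotopic_mass(sequence, table)
    return (m + charge * table.proton_mass) / charge


def fragment_mzs(
    sequence: str, table: ResidueMassTable = STANDARD_TABLE
) -> tuple[np.ndarray, np.ndarray]:
    """Singly charged b- and y-ion series of a peptide.

    ``b_i`` is the N-terminal fragment of *i* residues plus a proton;
    ``y_i`` is the C-terminal fragment of *i* residues plus water and a
    proton.  Both series run ``i = 1 .. n-1`` and are ascending in *i*.
    """
    if len(sequence) < 2:
        raise ValueError("need at least two residues to fragment")
    masses = np.array([table.mass(c) for c in sequence])
    prefix = np.cumsum(masses[:-1])
    suffix = np.cumsum(masses[::-1][:-1])
    b = prefix + table.proton_mass
    y = suffix + table.water_mass + table.proton_mass
    return b, y


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *stream)))


@dataclass(frozen=True)
class SynthParams:
    """Acquisition layout and noise model for :func:`synth_run`.

    Defaults describe a small but structurally complete run: 10 survey scans
    over a 10-minute span, 2 precursors fragmented per survey, MS2 only.
    Identical seeds give identical runs.
    """

    n_ms1: int = 10
    peptides_per_ms1: int = 2
    sequence_pool: Sequence[str] = DEFAULT_POOL
    max_ms_level: int = 2
    rt_span: float = 10.0
    noise_sd: float = 0.3  # sigma of the log-normal intensity jitter
    seed: int = 0
    store_profile: bool = True  # MS1 as 5-point profile stencils vs centroids

    def __post_init__(self) -> None:
        if self.n_ms1 < 1 or self.peptides_per_ms1 < 1:
            raise ValueError("counts must be positive")
        if self.max_ms_level not in (2, 3):
            raise ValueError("max_ms_level must be 2 or 3")
        if not self.sequence_pool:
            raise ValueError("sequence pool is empty")


def synth_msms_spectrum(
    sequence: str,
    charge: int,
    scan_number: int,
    rt: float,
    params: SynthParams,
    precursor_scan: int | None = None,
    ms_level: int = 2,
    table: ResidueMassTable = STANDARD_TABLE,
) -> SpectrumRecord:
    """One centroid MS/MS spectrum: the peptide's b/y series with seeded
    log-normal intensities (base peak 1e4), a noise vector and a unit charge
    vector per centroid."""
    b, y = fragment_mzs(sequence, table)
    mz = np.concatenate([b, y])
    order = np.argsort(mz, kind="stable")
    mz = mz[order]
    rng = _rng(params.seed, scan_number)
    intensity = rng.lognormal(mean=0.0, sigma=0.5, size=mz.size)
    if params.noise_sd > 0:
        intensity *= np.exp(rng.normal(0.0, params.noise_sd, size=mz.size))
    intensity *= 1e4 / intensity.max()
    noise = rng.uniform(0.5, 2.0, size=mz.size) * np.sqrt(intensity)
    return SpectrumRecord(
        scan_number=scan_number,
        ms_level=ms_level,
        retention_time=rt,
        mz=mz,
        intensity=intensity,
        precursor_mz=precursor_mz(sequence, charge, table),
        precursor_charge=charge,
        precursor_scan=precursor_scan,
        filter_string=(
            f"FTMS + c ESI d Full ms{ms_level} "
            f"{precursor_mz(sequence, charge, table):.4f}@hcd28.00"
        ),
        is_centroid=True,
        noise=noise,
        charge=np.full(mz.size, 1, dtype=np.int32),
    )


def _ms1_spectrum(
    scan_number: int,
    rt: float,
    params: SynthParams,
    table: ResidueMassTable,
) -> SpectrumRecord:
    """Survey scan showing every pool peptide as a doubly charged precursor,
    either as a 5-point Gaussian profile stencil in m/z or as one centroid."""
    rng = _rng(params.seed, scan_number)
    mzs: list[float] = []
    intensities: list[float] = []
    for k, seq in enumerate(params.sequence_pool):
        center = precursor_mz(seq, 2, table)
        # each peptide elutes as a Gaussian over the run, apex spread evenly
        apex = (k + 0.5) / len(params.sequence_pool) * params.rt_span
        elution = np.exp(-0.5 * ((rt - apex) / (0.15 * params.rt_span)) ** 2)
        amplitude = 1e6 * elution
        if params.noise_sd > 0:
            amplitude *= np.exp(rng.normal(0.0, params.noise_sd))
        if params.store_profile:
            offsets = np.linspace(-0.02, 0.02, 5)
            shape = np.exp(-0.5 * (offsets / 0.01) ** 2)
            mzs.extend(center + offsets)
            intensities.extend(amplitude * shape)
        else:
            mzs.append(center)
            intensities.append(amplitude)
    order = np.argsort(mzs, kind="stable")
    return SpectrumRecord(
        scan_number=scan_number,
        ms_level=1,
        retention_time=rt,
        mz=np.asarray(mzs)[order],
        intensity=np.asarray(intensities)[order],
        filter_string="FTMS + p ESI Full ms [300.00-2000.00]",
        is_centroid=not params.store_profile,
    )


def synth_run(params: SynthParams = SynthParams()) -> RunData:
    """Generate a deterministic data-dependent LC-MS/MS run.

    Scan numbers are sequential from 1; retention times are evenly spaced
    over ``rt_span``; every MS2 (and MS3) scan immediately follows, and
    references, its parent scan.  Output always satisfies
    :func:`~mzhdf.model.validate_run`.
    """
    table = STANDARD_TABLE
    pool = list(params.sequence_pool)
    picker = _rng(params.seed, 0xA11CE)

    per_cycle = 1 + params.peptides_per_ms1 * (2 if params.max_ms_level == 3 else 1)
    n_scans = params.n_ms1 * per_cycle
    rts = np.linspace(0.0, params.rt_span, n_scans, endpoint=False)

    spectra: list[SpectrumRecord] = []
    scan = 0
    for _cycle in range(params.n_ms1):
        scan += 1
        ms1 = _ms1_spectrum(scan, float(rts[scan - 1]), params, table)
        spectra.append(ms1)
        ms1_scan = scan
        chosen = picker.choice(
            len(pool), size=params.peptides_per_ms1,
            replace=params.peptides_per_ms1 > len(pool),
        )
        for idx in chosen:
            seq = pool[int(idx)]
            scan += 1
            ms2 = synth_msms_spectrum(
                seq, 2, scan, float(rts[scan - 1]), params,
                precursor_scan=ms1_scan, ms_level=2, table=table,
            )
            spectra.append(ms2)
            if params.max_ms_level == 3:
                ms2_scan = scan
                scan += 1
                # fragment the longest y-ion: the C-terminal subsequence
                sub = seq[-(len(seq) - 1):] if len(seq) > 2 else seq
                ms3 = synth_msms_spectrum(
                    sub, 1, scan, float(rts[scan - 1]), params,
                    precursor_scan=ms2_scan, ms_level=3, table=table,
                )
                spectra.append(ms3)
    return RunData(
        spectra=spectra,
        source_file=f"synthetic(seed={params.seed})",
        instrument_model="synthetic orbitrap",
        centroid_export=not params.store_profile,
    )
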