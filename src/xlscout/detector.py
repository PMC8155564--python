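"""Detection of cross-link spectra via stump-ion doublets.

A peptide carrying the light vs the heavy linker stump appears as a peak pair
separated by ``(heavy - light) / z``.  A full doublet pins down that peptide's
neutral mass; two complementary doublets (or a doublet plus a single stump ion
of the partner) that together with the intact linker mass reconstruct the
precursor mass flag the spectrum as a cross-link spectrum and hand the two
peptide-mass hypotheses to the search.

Three modes are offered:

* ``evidence`` — requires ions from both peptides (two full doublets, or one
  full doublet plus a single light/heavy ion of the partner);
* ``indication`` — one full doublet suffices, the partner mass is inferred by
  subtraction from the precursor mass;
* ``combined`` — the union of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import C13_C12, PROTON, CrosslinkerSpec
from .spectra import Ms2Spectrum, Tolerance, match_peak

#: Partner masses below this (Da) are not plausible tryptic peptides.
MIN_PEPTIDE_MASS = 300.0

#: Bound on the O(peaks^2) doublet pairing.
MAX_PEAKS_FOR_DOUBLETS = 2000
#: Partial-evidence single ions are taken from this many most intense peaks.
MAX_SINGLE_PEAKS = 200


@dataclass
class PairingStats:
    """Instrumentation counters for the complexity contract of the pairing step."""

    doublet_pairs_examined: int = 0
    single_ion_combinations: int = 0
    spectra_processed: int = 0

    @property
    def total(self) -> int:
        return self.doublet_pairs_examined + self.single_ion_combinations


@dataclass(frozen=True)
class DoubletEvidence:
    """A light/heavy stump-peak pair implying one peptide's neutral mass."""

    peptide_neutral_mass: float
    charge: int
    light_peak_mz: float
    heavy_peak_mz: float | None
    completeness: str = "full"  # full | light_only | heavy_only


@dataclass(frozen=True)
class PrecursorHypothesis:
    """An alternative (monoisotopic-corrected) precursor neutral mass."""

    neutral_mass: float
    isotope_offset: int = 0
    verified_in_ms1: bool = False


@dataclass(frozen=True)
class MassPairHypothesis:
    """Two hypothesized peptide masses explaining the precursor; alpha >= beta."""

    mass_alpha: float
    mass_beta: float
    mode: str  # evidence | indication
    completeness: str = "full"  # full | light_only | heavy_only | inferred
    supporting: tuple[DoubletEvidence, ...] = ()

    @staticmethod
    def make(m1: float, m2: float, mode: str, completeness: str = "full",
             supporting: tuple[DoubletEvidence, ...] = ()) -> "MassPairHypothesis":
        a, b = (m1, m2) if m1 >= m2 else (m2, m1)
        return MassPairHypothesis(a, b, mode, completeness, supporting)

    @property
    def dedup_key(self) -> tuple[float, float]:
        return (round(self.mass_alpha, 3), round(self.mass_beta, 3))


def _trimmed_peaks(spectrum: Ms2Spectrum, max_peaks: int) -> tuple[np.ndarray, np.ndarray]:
    mz, it = spectrum.peaks_mz, spectrum.peaks_intensity
    if len(mz) > max_peaks:
        keep = np.sort(np.argsort(it)[-max_peaks:])
        mz, it = mz[keep], it[keep]
    return mz, it


def find_doublets(spectrum: Ms2Spectrum, linker: CrosslinkerSpec,
                  charge_range: range, doublet_tolerance: Tolerance,
                  ) -> list[DoubletEvidence]:
    """Find full light/heavy stump doublets at every charge in ``charge_range``.

    For charge ``z`` a peak pair (i, j) is a doublet when the observed gap
    matches ``(heavy - light)/z`` within the tolerance (ppm taken at the
    heavier peak).  The peptide neutral mass is inferred from the light peak:
    ``mz_i * z - z * proton - light_mass``.  Results are deduplicated by
    (mass rounded to 1 mDa, charge).
    """
    mz, _ = _trimmed_peaks(spectrum, MAX_PEAKS_FOR_DOUBLETS)
    out: dict[tuple[float, int], DoubletEvidence] = {}
    for z in charge_range:
        if z < 1:
            continue
        delta = linker.doublet_delta / z
        for i, light_mz in enumerate(mz):
            target = light_mz + delta
            w = doublet_tolerance.window(target)
            lo = int(np.searchsorted(mz, target - w, side="left"))
            hi = int(np.searchsorted(mz, target + w, side="right"))
            for j in range(lo, hi):
                if j == i:
                    continue
                mass = light_mz * z - z * PROTON - linker.light_mass
                if mass <= 0:
                    continue
                key = (round(mass, 3), z)
                if key not in out:
                    out[key] = DoubletEvidence(
                        peptide_neutral_mass=mass, charge=z,
                        light_peak_mz=float(light_mz), heavy_peak_mz=float(mz[j]))
    return sorted(out.values(), key=lambda d: (d.peptide_neutral_mass, d.charge))


def _relation_holds(m1: float, m2: float, precursor_mass: float,
                    linker: CrosslinkerSpec, t_d: Tolerance) -> bool:
    return abs(m1 + m2 + linker.intact_mass - precursor_mass) <= t_d.window(precursor_mass)


def detect_evidence_pairs(doublets: list[DoubletEvidence], spectrum: Ms2Spectrum,
                          precursor_mass: float, linker: CrosslinkerSpec,
                          t_d: Tolerance, charge_range: range,
                          stats: PairingStats | None = None,
                          ) -> list[MassPairHypothesis]:
    """Evidence mode: require ions from both peptides.

    (a) Every pair of full doublets whose masses plus the intact linker mass
    reconstruct the precursor mass within ``t_d`` is emitted.  (b) Every full
    doublet combined with a single intense peak read as the light *or* heavy
    stump ion of the partner (both readings, at every charge) that satisfies
    the same relation is emitted as partial evidence.
    """
    out: dict[tuple[float, float], MassPairHypothesis] = {}
    for i in range(len(doublets)):
        for j in range(i + 1, len(doublets)):
            if stats is not None:
                stats.doublet_pairs_examined += 1
            m1, m2 = doublets[i].peptide_neutral_mass, doublets[j].peptide_neutral_mass
            if _relation_holds(m1, m2, precursor_mass, linker, t_d):
                h = MassPairHypothesis.make(m1, m2, "evidence", "full",
                                            (doublets[i], doublets[j]))
                out.setdefault(h.dedup_key, h)

    # Partial evidence: one full doublet plus a lone stump ion of the partner.
    mz, it = _trimmed_peaks(spectrum, MAX_PEAKS_FOR_DOUBLETS)
    doublet_mzs = {round(d.light_peak_mz, 6) for d in doublets}
    doublet_mzs |= {round(d.heavy_peak_mz, 6) for d in doublets if d.heavy_peak_mz}
    unassigned = [k for k in range(len(mz)) if round(float(mz[k]), 6) not in doublet_mzs]
    if len(unassigned) > MAX_SINGLE_PEAKS:
        order = np.argsort(it[unassigned])[::-1][:MAX_SINGLE_PEAKS]
        unassigned = [unassigned[int(o)] for o in order]
    for d in doublets:
        m1 = d.peptide_neutral_mass
        for k in unassigned:
            peak_mz = float(mz[k])
            for z in charge_range:
                if z < 1:
                    continue
                for stump, completeness in ((linker.light_mass, "light_only"),
                                            (linker.heavy_mass, "heavy_only")):
                    if stats is not None:
                        stats.single_ion_combinations += 1
                    m2 = peak_mz * z - z * PROTON - stump
                    if m2 < MIN_PEPTIDE_MASS:
                        continue
                    if _relation_holds(m1, m2, precursor_mass, linker, t_d):
                        h = MassPairHypothesis.make(m1, m2, "evidence",
                                                    completeness, (d,))
                        out.setdefault(h.dedup_key, h)
    return sorted(out.values(), key=lambda h: h.dedup_key)


def detect_indication_pairs(doublets: list[DoubletEvidence], spectrum: Ms2Spectrum,
                            precursor_mass: float, linker: CrosslinkerSpec,
                            t_d: Tolerance, charge_range: range,
                            single_ion_tolerance: Tolerance | None = None,
                            ) -> list[MassPairHypothesis]:
    """Indication mode: infer the missing partner from the precursor mass.

    For each full doublet of mass ``m1`` the partner mass is
    ``precursor - intact - m1``; pairs with an implausibly small partner are
    dropped.  The four light/heavy single-ion combinations are checked only to
    annotate supporting ions of the inferred partner, not to gate emission.
    """
    out: dict[tuple[float, float], MassPairHypothesis] = {}
    tol = single_ion_tolerance or t_d
    for d in doublets:
        m1 = d.peptide_neutral_mass
        m2 = precursor_mass - linker.intact_mass - m1
        if m2 < MIN_PEPTIDE_MASS:
            continue
        supporting = [d]
        for z in charge_range:
            if z < 1:
                continue
            for stump, completeness in ((linker.light_mass, "light_only"),
                                        (linker.heavy_mass, "heavy_only")):
                idx = match_peak(spectrum, (m2 + stump + z * PROTON) / z, tol)
                if idx is not None:
                    supporting.append(DoubletEvidence(
                        peptide_neutral_mass=m2, charge=z,
                        light_peak_mz=float(spectrum.peaks_mz[idx]),
                        heavy_peak_mz=None, completeness=completeness))
        h = MassPairHypothesis.make(m1, m2, "indication", "inferred",
                                    tuple(supporting))
        out.setdefault(h.dedup_key, h)
    return sorted(out.values(), key=lambda h: h.dedup_key)


def detect_diagnostic_ions(spectrum: Ms2Spectrum, linker: CrosslinkerSpec,
                           tolerance: Tolerance) -> dict[float, bool]:
    """Which configured linker diagnostic m/z values are present in the spectrum.

    Diagnostic ions are advisory: they support the cross-link classification
    but never replace the doublet requirement.
    """
    return {dz: match_peak(spectrum, dz, tolerance) is not None
            for dz in linker.diagnostic_ions}


def precursor_hypotheses(spectrum: Ms2Spectrum, max_offsets: int = 0,
                         mode: str = "assumed",
                         ms1: Ms2Spectrum | None = None,
                         ms1_tolerance: Tolerance | None = None,
                         charge: int | None = None) -> list[PrecursorHypothesis]:
    """Alternative precursors for monoisotopic-peak misassignment.

    Offsets 0, -1, ..., -max_offsets shift the neutral mass by multiples of
    the C13-C12 difference.  In ``ms1-verified`` mode a shifted hypothesis is
    kept only if a matching peak exists in the supplied MS1 scan; in
    ``assumed`` mode all are kept.
    """
    if mode not in ("assumed", "ms1-verified"):
        raise ValueError(f"unknown precursor mode {mode!r}")
    if mode == "ms1-verified" and ms1 is None:
        raise ValueError("ms1-verified precursor mode requires an MS1 spectrum")
    z = charge if charge is not None else spectrum.precursor_charge
    base = spectrum.precursor_neutral_mass(z)
    out = []
    for k in range(0, max_offsets + 1):
        neutral = base - k * C13_C12
        verified = False
        if mode == "ms1-verified" and k > 0:
            shifted_mz = (neutral + z * PROTON) / z
            tol = ms1_tolerance or Tolerance(5.0, "ppm")
            if match_peak(ms1, shifted_mz, tol) is None:
                continue
            verified = True
        out.append(PrecursorHypothesis(neutral_mass=neutral, isotope_offset=-k,
                                       verified_in_ms1=verified))
    return out


@dataclass
class DetectorConfig:
    """Tunables of the doublet detector."""

    mode: str = "combined"  # evidence | indication | combined
    doublet_tolerance: Tolerance = field(default_factory=lambda: Tolerance(10.0, "ppm"))
    pair_tolerance: Tolerance = field(default_factory=lambda: Tolerance(5.0, "ppm"))
    max_isotope_offsets: int = 0
    precursor_mode: str = "assumed"
    require_diagnostic: bool = False
    diagnostic_tolerance: Tolerance = field(default_factory=lambda: Tolerance(10.0, "ppm"))


def detect(spectrum: Ms2Spectrum, linker: CrosslinkerSpec,
           config: DetectorConfig = DetectorConfig(),
           precursor_mass: float | None = None,
           charge: int | None = None,
           stats: PairingStats | None = None) -> list[MassPairHypothesis]:
    """Classify one spectrum and extract peptide-mass-pair hypotheses.

    An empty result classifies the spectrum as a non-cross-link spectrum; the
    search skips it.  ``combined`` mode is the deduplicated union of evidence
    and indication hypotheses.
    """
    if config.mode not in ("evidence", "indication", "combined"):
        raise ValueError(f"unknown detector mode {config.mode!r}")
    z = charge if charge is not None else spectrum.precursor_charge
    if z is None:
        raise ValueError("precursor charge required (enumerate upstream)")
    if precursor_mass is None:
        precursor_mass = spectrum.precursor_neutral_mass(z)
    if config.require_diagnostic and linker.diagnostic_ions:
        flags = detect_diagnostic_ions(spectrum, linker, config.diagnostic_tolerance)
        if not any(flags.values()):
            return []
    charge_range = range(1, max(z, 2))  # fragment cannot out-charge its precursor
    doublets = find_doublets(spectrum, linker, charge_range, config.doublet_tolerance)
    if stats is not None:
        stats.spectra_processed += 1
    out: dict[tuple[float, float], MassPairHypothesis] = {}
    if config.mode in ("evidence", "combined"):
        for h in detect_evidence_pairs(doublets, spectrum, precursor_mass, linker,
                                       config.pair_tolerance, charge_range, stats):
            out.setdefault(h.dedup_key, h)
    if config.mode in ("indication", "combined"):
        for h in detect_indication_pairs(doublets, spectrum, precursor_mass, linker,
                                         config.pair_tolerance, charge_range,
                                         config.doublet_tolerance):
            out.setdefault(h.dedup_key, h)
    return sorted(out.values(), key=lambda h: h.dedup_key)
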