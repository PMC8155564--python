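"""Peptide scoring and cross-link spectrum-match (CSM) assembly.

Each hypothesized peptide mass from the detector is looked up in the candidate
index; every candidate is scored against the spectrum with a probability-based
score: the binomial tail probability that ``k`` of ``n`` theoretical fragments
match by chance, weighted by the explained intensity and ``-log10``
transformed.  The two candidate lists are combined under the precursor-mass
constraint; the pair score of a CSM is the *minimum* of the two peptide
scores, and the highest-scoring pair per spectrum is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import AA_MONO, PROTON, WATER, CandidateIndex, CrosslinkerSpec, Peptide
from .detector import (DetectorConfig, PairingStats, detect,
                       precursor_hypotheses)
from .spectra import Ms2Spectrum, Tolerance

# Bounds on the per-fragment chance-match probability.
P_MIN, P_MAX = 1e-6, 0.5


@dataclass(frozen=True)
class FragmentModel:
    """Which fragment ion series and charges are generated."""

    series: tuple[str, ...] = ("b", "y")
    charges: tuple[int, ...] = (1, 2)
    include_intact_partner: bool = False  # fragment + intact linker + whole partner

    def __post_init__(self) -> None:
        if not self.series:
            raise ValueError("at least one ion series must be enabled")


def theoretical_fragments(peptide: Peptide, link_position: int,
                          linker: CrosslinkerSpec,
                          model: FragmentModel = FragmentModel(),
                          ) -> tuple[np.ndarray, list[str]]:
    """Theoretical b/y fragment m/z values for a linked peptide.

    Fragments containing the link site are emitted twice — once with the light
    and once with the heavy stump mass added (the linker cleaves on either
    side); fragments without the site are unmodified.  Duplicate m/z values
    (to 1e-6) are merged.
    """
    seq = peptide.sequence
    n = len(seq)
    if not 1 <= link_position <= n:
        raise ValueError(f"link position {link_position} outside peptide of length {n}")
    mods = peptide.mod_map
    residue = [AA_MONO[a] + mods.get(i + 1, 0.0) for i, a in enumerate(seq)]
    prefix = np.cumsum(residue)

    out: dict[float, str] = {}

    def emit(neutral: float, label: str) -> None:
        for z in model.charges:
            mz = (neutral + z * PROTON) / z
            out.setdefault(round(mz, 6), f"{label}^{z}")

    stumps = ((linker.light_mass, "+L"), (linker.heavy_mass, "+H"))
    for i in range(1, n):  # b_i / y_(n-i) at cleavage after residue i
        if "b" in model.series:
            b_neutral = float(prefix[i - 1])
            if link_position <= i:
                for s, tag in stumps:
                    emit(b_neutral + s, f"b{i}{tag}")
            else:
                emit(b_neutral, f"b{i}")
        if "y" in model.series:
            y_len = n - i
            y_neutral = float(prefix[-1] - prefix[i - 1]) + WATER
            if link_position > i:
                for s, tag in stumps:
                    emit(y_neutral + s, f"y{y_len}{tag}")
            else:
                emit(y_neutral, f"y{y_len}")
    mzs = np.array(sorted(out), dtype=float)
    return mzs, [out[m] for m in sorted(out)]


def _binomial_tail_log10(n: int, k: int, p: float) -> float:
    """log10 of P(X >= k) for X ~ Binomial(n, p), by log-space term summation."""
    if k <= 0:
        return 0.0
    if k == n:
        return n * math.log10(p)
    lp, lq = math.log(p), math.log1p(-p)
    lgn = math.lgamma(n + 1)
    logs = [lgn - math.lgamma(i + 1) - math.lgamma(n - i + 1) + i * lp + (n - i) * lq
            for i in range(k, n + 1)]
    m = max(logs)
    return (m + math.log(math.fsum(math.exp(x - m) for x in logs))) / math.log(10)


def binomial_score(n: int, k: int, p: float, explained_fraction: float) -> float:
    """Score = -log10 P(X >= k | n, p) weighted by explained intensity, floored at 0."""
    return max(-_binomial_tail_log10(n, k, p) * explained_fraction, 0.0)


def match_score(spectrum: Ms2Spectrum, fragment_mzs: np.ndarray,
                ms2_tolerance: Tolerance) -> tuple[float, int, float]:
    """Binomial match score of a fragment list against a spectrum.

    Returns ``(score, matched_count, explained_intensity_fraction)``.  The
    per-fragment chance-match probability is
    ``p = clamp(n_peaks * 2 * tol_Da / (mz_max - mz_min), 1e-6, 0.5)`` with the
    ppm tolerance converted to Da at the centre of the observed m/z range; the
    score is ``-log10 P(X >= k | n, p)`` weighted by the fraction of total
    spectrum intensity carried by matched peaks, floored at 0.
    """
    n = len(fragment_mzs)
    if n == 0 or len(spectrum) == 0:
        return 0.0, 0, 0.0
    mz = spectrum.peaks_mz
    w_of = ms2_tolerance.window
    lo = np.searchsorted(mz, fragment_mzs - np.array([w_of(f) for f in fragment_mzs]),
                         side="left")
    hi = np.searchsorted(mz, fragment_mzs + np.array([w_of(f) for f in fragment_mzs]),
                         side="right")
    matched_frag = hi > lo
    k = int(matched_frag.sum())
    matched_peaks: set[int] = set()
    for f in np.flatnonzero(matched_frag):
        matched_peaks.update(range(int(lo[f]), int(hi[f])))
    total = spectrum.total_intensity()
    frac = float(spectrum.peaks_intensity[sorted(matched_peaks)].sum() / total) \
        if total > 0 else 0.0
    span = float(mz[-1] - mz[0])
    p = P_MAX if span <= 0 else min(max(len(mz) * 2.0 * w_of(float(mz.mean())) / span,
                                        P_MIN), P_MAX)
    return binomial_score(n, k, p, frac), k, frac


@dataclass(frozen=True)
class PeptideHit:
    """One candidate peptide scored against a spectrum at its best link site."""

    peptide: Peptide
    link_position: int
    score: float
    matched_peak_count: int
    theoretical_peak_count: int
    explained_intensity_fraction: float


@dataclass(frozen=True)
class CSM:
    """A cross-link spectrum match: one spectrum, two scored peptides.

    ``score`` is the minimum of the two peptide scores; ``alpha`` is the
    higher-scoring peptide.
    """

    scan_id: str
    alpha: PeptideHit
    beta: PeptideHit
    score: float
    precursor_error_ppm: float
    decoy_class: str  # TT | TD | DD
    link_class: str  # intra | inter
    mode: str
    precursor_charge: int = 0
    isotope_offset: int = 0

    @property
    def is_decoy(self) -> bool:
        return self.decoy_class != "TT"


def classify_pair(a: Peptide, b: Peptide) -> str:
    if not a.is_decoy and not b.is_decoy:
        return "TT"
    if a.is_decoy and b.is_decoy:
        return "DD"
    return "TD"


def _link_class(a: Peptide, b: Peptide) -> str:
    accs_a = {acc for acc, _ in a.protein_locations}
    accs_b = {acc for acc, _ in b.protein_locations}
    return "intra" if accs_a & accs_b else "inter"


def search_candidates(index: CandidateIndex, peptide_mass: float,
                      mass_tolerance: Tolerance, linker: CrosslinkerSpec,
                      spectrum: Ms2Spectrum, top_n: int = 5,
                      ms2_tolerance: Tolerance = Tolerance(10.0, "ppm"),
                      model: FragmentModel = FragmentModel(),
                      ) -> list[PeptideHit]:
    """Score index candidates near ``peptide_mass`` and keep the top N.

    The hypothesized mass already excludes the stump (it was subtracted during
    doublet inference), so candidates are matched on their plain modified
    neutral mass.  Every valid link site of a candidate is scored; the best
    site is kept.  Hits are sorted by score descending.
    """
    hits: list[PeptideHit] = []
    for i in index.query(peptide_mass, mass_tolerance):
        pep = index.peptides[i]
        best: PeptideHit | None = None
        for site in index.sites(i):
            frags, _ = theoretical_fragments(pep, site, linker, model)
            score, k, frac = match_score(spectrum, frags, ms2_tolerance)
            hit = PeptideHit(pep, site, score, k, len(frags), frac)
            if best is None or (hit.score, hit.explained_intensity_fraction) > \
                    (best.score, best.explained_intensity_fraction):
                best = hit
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, -h.explained_intensity_fraction,
                             h.peptide.sequence, h.peptide.modifications))
    return hits[:top_n]


def _tie_key(csm: CSM) -> tuple:
    """Sort key for CSM preference: higher score, higher summed explained
    intensity, TT over TD over DD, then lexicographic sequences."""
    decoy_rank = {"TT": 0, "TD": 1, "DD": 2}[csm.decoy_class]
    return (-csm.score,
            -(csm.alpha.explained_intensity_fraction
              + csm.beta.explained_intensity_fraction),
            decoy_rank, csm.alpha.peptide.sequence, csm.beta.peptide.sequence)


def _self_pair_allowed(pep: Peptide, allow_homodimers: bool) -> bool:
    return allow_homodimers or len(pep.protein_locations) >= 2


def combine_and_select(hits_alpha: list[PeptideHit], hits_beta: list[PeptideHit],
                       precursor_mass: float, linker: CrosslinkerSpec,
                       t_d: Tolerance, scan_id: str = "", mode: str = "",
                       allow_homodimers: bool = False,
                       precursor_charge: int = 0, isotope_offset: int = 0,
                       ) -> CSM | None:
    """Form all candidate pairs obeying the precursor relation; keep the best.

    The pair score is the minimum of the two peptide scores; ties are broken
    by summed explained intensity, then target class, then sequence.
    """
    best: CSM | None = None
    best_key = None
    for ha in hits_alpha:
        for hb in hits_beta:
            ma, mb = ha.peptide.neutral_mass, hb.peptide.neutral_mass
            err = ma + mb + linker.intact_mass - precursor_mass
            if abs(err) > t_d.window(precursor_mass):
                continue
            if ha.peptide == hb.peptide and not _self_pair_allowed(
                    ha.peptide, allow_homodimers):
                continue
            a, b = (ha, hb) if ha.score >= hb.score else (hb, ha)
            csm = CSM(scan_id=scan_id, alpha=a, beta=b,
                      score=min(ha.score, hb.score),
                      precursor_error_ppm=err / precursor_mass * 1e6,
                      decoy_class=classify_pair(a.peptide, b.peptide),
                      link_class=_link_class(a.peptide, b.peptide),
                      mode=mode, precursor_charge=precursor_charge,
                      isotope_offset=isotope_offset)
            key = _tie_key(csm)
            if best_key is None or key < best_key:
                best, best_key = csm, key
    return best


@dataclass
class SearchConfig:
    """Tunables of the search step."""

    top_n: int = 5
    ms2_tolerance: Tolerance = field(default_factory=lambda: Tolerance(10.0, "ppm"))
    peptide_mass_tolerance: Tolerance = field(default_factory=lambda: Tolerance(20.0, "ppm"))
    fragment_model: FragmentModel = field(default_factory=FragmentModel)
    allow_homodimers: bool = False
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    charge_enumeration: tuple[int, ...] = (2, 3, 4, 5, 6)  # when CHARGE is absent


def search_spectrum(spectrum: Ms2Spectrum, index: CandidateIndex,
                    linker: CrosslinkerSpec,
                    config: SearchConfig = SearchConfig(),
                    stats: PairingStats | None = None) -> CSM | None:
    """Best CSM for one spectrum over all detector and precursor hypotheses.

    Spectra without doublet hypotheses are classified non-cross-link and
    return None.  Spectra lacking a precursor charge are searched once per
    assumed charge.
    """
    charges = ([spectrum.precursor_charge] if spectrum.charge_known
               else list(config.charge_enumeration))
    best: CSM | None = None
    best_key = None
    score_cache: dict[float, list[PeptideHit]] = {}

    def hits_for(mass: float) -> list[PeptideHit]:
        key = round(mass, 4)
        if key not in score_cache:
            score_cache[key] = search_candidates(
                index, mass, config.peptide_mass_tolerance, linker, spectrum,
                config.top_n, config.ms2_tolerance, config.fragment_model)
        return score_cache[key]

    for z in charges:
        for ph in precursor_hypotheses(spectrum, config.detector.max_isotope_offsets,
                                       config.detector.precursor_mode, charge=z):
            hypotheses = detect(spectrum, linker, config.detector,
                                precursor_mass=ph.neutral_mass, charge=z,
                                stats=stats)
            for hyp in hypotheses:
                csm = combine_and_select(
                    hits_for(hyp.mass_alpha), hits_for(hyp.mass_beta),
                    ph.neutral_mass, linker, config.detector.pair_tolerance,
                    scan_id=spectrum.scan_id, mode=hyp.mode,
                    allow_homodimers=config.allow_homodimers,
                    precursor_charge=z, isotope_offset=ph.isotope_offset)
                if csm is None:
                    continue
                key = _tie_key(csm)
                if best_key is None or key < best_key:
                    best, best_key = csm, key
    return best
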