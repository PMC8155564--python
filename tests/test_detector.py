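"""Doublet detection, evidence/indication pairing and precursor hypotheses."""

import numpy as np
import pytest

from xlscout.chem import C13_C12, PROTON
from xlscout.detector import (DetectorConfig, detect, detect_diagnostic_ions,
                              detect_evidence_pairs, detect_indication_pairs,
                              find_doublets, precursor_hypotheses)
from xlscout.simulate import SimulationParams, generate_database, generate_spectra
from xlscout.spectra import Tolerance

from conftest import make_spectrum

TOL = Tolerance(10.0, "ppm")
T_D = Tolerance(0.01, "Da")


def doublet_spectrum(masses_charges, linker, extra=(), precursor_mz=1200.0,
                     charge=4):
    """Spectrum containing the full light/heavy doublet for each (mass, z)."""
    mzs = list(extra)
    for m, z in masses_charges:
        mzs.append((m + linker.light_mass + z * PROTON) / z)
        mzs.append((m + linker.heavy_mass + z * PROTON) / z)
    return make_spectrum(sorted(mzs), precursor_mz=precursor_mz, charge=charge)


class TestFindDoublets:
    @pytest.mark.parametrize("z", [1, 2, 3, 4])
    def test_recovers_planted_mass_at_any_charge(self, dsso, z):
        s = doublet_spectrum([(1000.0, z)], dsso, charge=5)
        got = find_doublets(s, dsso, range(1, 5), TOL)
        assert [(round(d.peptide_neutral_mass, 4), d.charge) for d in got] == \
            [(1000.0, z)]

    def test_literal_mz_values(self, dsso):
        s = make_spectrum([1055.017846, 1105.000476], charge=3)
        (d,) = find_doublets(s, dsso, range(1, 3), TOL)
        assert d.peptide_neutral_mass == pytest.approx(1000.0, abs=1e-4)
        assert d.charge == 1

    def test_empty_spectrum(self, dsso):
        s = make_spectrum([])
        assert find_doublets(s, dsso, range(1, 4), TOL) == []

    def test_light_and_heavy_inference_agree(self, dsso):
        """Complementarity: both stump peaks imply the same peptide mass."""
        for z in (1, 2, 3):
            s = doublet_spectrum([(1500.0, z)], dsso, charge=4)
            (d,) = find_doublets(s, dsso, range(1, 4), TOL)
            from_light = d.light_peak_mz * z - z * PROTON - dsso.light_mass
            from_heavy = d.heavy_peak_mz * z - z * PROTON - dsso.heavy_mass
            assert abs(from_light - from_heavy) <= TOL.window(d.heavy_peak_mz)


class TestEvidencePairs:
    def test_complementary_doublets_pair(self, dsso):
        s = doublet_spectrum([(1000.0, 1), (1500.0, 1)], dsso)
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        pairs = detect_evidence_pairs(doublets, s, 2658.00377, dsso, T_D,
                                      range(1, 3))
        full = [p for p in pairs if p.completeness == "full"]
        assert len(full) == 1
        assert (round(full[0].mass_alpha, 3), round(full[0].mass_beta, 3)) == \
            (1500.0, 1000.0)

    def test_wrong_precursor_rejected(self, dsso):
        s = doublet_spectrum([(1000.0, 1), (1500.0, 1)], dsso)
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        pairs = detect_evidence_pairs(doublets, s, 2660.0, dsso, T_D, range(1, 3))
        assert [p for p in pairs if p.completeness == "full"] == []

    def test_partial_evidence_single_light_ion(self, dsso):
        # full doublet at 1000 plus lone light-stump ion of a 1500 Da partner
        lone = (1500.0 + dsso.light_mass + PROTON) / 1
        s = doublet_spectrum([(1000.0, 1)], dsso, extra=[lone])
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        pairs = detect_evidence_pairs(doublets, s, 2658.00377, dsso, T_D,
                                      range(1, 3))
        assert any(p.completeness == "light_only"
                   and p.mass_alpha == pytest.approx(1500.0, abs=1e-3)
                   for p in pairs)

    def test_sum_rule_holds_on_every_pair(self, dsso):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m1, m2 = rng.uniform(600, 2000, size=2)
            precursor = m1 + m2 + dsso.intact_mass
            s = doublet_spectrum([(m1, 1), (m2, 2)], dsso)
            doublets = find_doublets(s, dsso, range(1, 4), TOL)
            for p in detect_evidence_pairs(doublets, s, precursor, dsso, T_D,
                                           range(1, 4)):
                assert abs(p.mass_alpha + p.mass_beta + dsso.intact_mass
                           - precursor) <= T_D.window(precursor)


class TestIndicationPairs:
    def test_partner_inferred_by_subtraction(self, dsso):
        s = doublet_spectrum([(1000.0, 1)], dsso)
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        pairs = detect_indication_pairs(doublets, s, 2658.00377, dsso, T_D,
                                        range(1, 3))
        assert len(pairs) == 1
        assert pairs[0].mass_beta == pytest.approx(1000.0, abs=1e-3)
        assert pairs[0].mass_alpha == pytest.approx(1500.0, abs=1e-3)

    def test_undersized_partner_dropped(self, dsso):
        s = doublet_spectrum([(2600.0, 2)], dsso)
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        assert detect_indication_pairs(doublets, s, 2658.00377, dsso, T_D,
                                       range(1, 3)) == []

    def test_two_consistent_doublets_give_one_canonical_pair(self, dsso):
        s = doublet_spectrum([(1000.0, 1), (1500.0, 1)], dsso)
        doublets = find_doublets(s, dsso, range(1, 3), TOL)
        pairs = detect_indication_pairs(doublets, s, 2658.00377, dsso, T_D,
                                        range(1, 3))
        keys = {p.dedup_key for p in pairs}
        assert keys == {(1500.0, 1000.0)}


class TestModes:
    def _spectra(self, dsso):
        both = doublet_spectrum([(1000.0, 1), (1500.0, 1)], dsso,
                                precursor_mz=(2658.00377 + 3 * PROTON) / 3,
                                charge=3)
        one = doublet_spectrum([(1000.0, 1)], dsso,
                               precursor_mz=(2658.00377 + 3 * PROTON) / 3,
                               charge=3)
        return both, one

    def test_mode_lattice(self, dsso):
        """evidence and indication hypotheses are both subsets of combined."""
        for s in self._spectra(dsso):
            ev = {h.dedup_key for h in detect(s, dsso, DetectorConfig(mode="evidence"))}
            ind = {h.dedup_key for h in detect(s, dsso, DetectorConfig(mode="indication"))}
            comb = {h.dedup_key for h in detect(s, dsso, DetectorConfig(mode="combined"))}
            assert ev <= comb and ind <= comb

    def test_single_doublet_needs_indication(self, dsso):
        _, one = self._spectra(dsso)
        assert detect(one, dsso, DetectorConfig(mode="evidence")) == []
        assert detect(one, dsso, DetectorConfig(mode="indication")) != []

    def test_unknown_mode_rejected(self, dsso):
        s = make_spectrum([100.0])
        with pytest.raises(ValueError):
            detect(s, dsso, DetectorConfig(mode="bogus"))


class TestDiagnosticIons:
    def test_flags_configured_ions(self, dsso):
        from dataclasses import replace
        linker = replace(dsso, diagnostic_ions=(222.1, 333.2))
        s = make_spectrum([222.1, 500.0])
        flags = detect_diagnostic_ions(s, linker, TOL)
        assert flags == {222.1: True, 333.2: False}

    def test_no_diagnostic_ions_configured(self, dsso):
        assert detect_diagnostic_ions(make_spectrum([100.0]), dsso, TOL) == {}

    def test_diagnostic_alone_does_not_rescue_spectrum(self, dsso):
        from dataclasses import replace
        linker = replace(dsso, diagnostic_ions=(222.1,))
        s = make_spectrum([222.1])  # diagnostic present, no doublets
        assert detect(s, linker, DetectorConfig(mode="combined")) == []


class TestPrecursorHypotheses:
    def test_offset_count(self):
        s = make_spectrum([100.0], precursor_mz=887.341527, charge=3)
        assert len(precursor_hypotheses(s, max_offsets=2, mode="assumed")) == 3
        assert len(precursor_hypotheses(s, max_offsets=0, mode="assumed")) == 1

    def test_offset_shifts_by_c13(self):
        s = make_spectrum([100.0], precursor_mz=(2658.00377 + 3 * PROTON) / 3,
                          charge=3)
        hyps = precursor_hypotheses(s, max_offsets=1, mode="assumed")
        assert hyps[1].neutral_mass == pytest.approx(2658.00377 - C13_C12, abs=1e-5)
        assert hyps[1].isotope_offset == -1

    def test_ms1_verified_requires_ms1(self):
        s = make_spectrum([100.0])
        with pytest.raises(ValueError):
            precursor_hypotheses(s, max_offsets=1, mode="ms1-verified")

    def test_ms1_verified_keeps_only_observed(self):
        s = make_spectrum([100.0], precursor_mz=1000.0, charge=2)
        shifted_mz = 1000.0 - C13_C12 / 2
        ms1 = make_spectrum([shifted_mz])
        hyps = precursor_hypotheses(s, max_offsets=3, mode="ms1-verified", ms1=ms1)
        assert [h.isotope_offset for h in hyps] == [0, -1]


def _planted_set(t):
    planted = set()
    if t.alpha_doublet_charge:
        planted.add((round(t.alpha_mass, 4), t.alpha_doublet_charge))
    if t.beta_doublet_charge:
        planted.add((round(t.beta_mass, 4), t.beta_doublet_charge))
    return planted


class TestPlantedDoubletOracle:
    def test_doublet_only_spectra_recovered_exactly(self, dsso):
        """With nothing but the planted stump doublets in the spectrum, the
        detector recovers exactly the planted (mass, charge) set."""
        params = SimulationParams(seed=17, n_proteins=4, protein_length=200,
                                  n_spectra=40, fragment_coverage=0.0,
                                  doublet_probability=1.0, noise_peaks=0,
                                  fragment_ppm_error=0.0, precursor_ppm_error=0.0)
        targets, _ = generate_database(params)
        spectra, truth = generate_spectra(targets, params)
        for s, t in zip(spectra, truth):
            got = find_doublets(s, dsso, range(1, t.precursor_charge),
                                Tolerance(10.0, "ppm"))
            found = {(round(d.peptide_neutral_mass, 4), d.charge) for d in got}
            assert found == _planted_set(t)

    def test_planted_doublets_found_despite_fragment_ladders(self, clean_dataset,
                                                             dsso):
        """Full-coverage spectra additionally contain stump doublets of
        site-containing fragments; the planted peptide doublets must still all
        be found (the precursor-sum relation later discards fragment pairs)."""
        _, spectra, truth = clean_dataset
        for s, t in zip(spectra, truth):
            got = find_doublets(s, dsso, range(1, t.precursor_charge),
                                Tolerance(10.0, "ppm"))
            found = {(round(d.peptide_neutral_mass, 4), d.charge) for d in got}
            assert _planted_set(t) <= found
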