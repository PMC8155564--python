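import numpy as np
import pytest

from xlscout.chem import LINKERS
from xlscout.simulate import SimulationParams, generate_database, generate_spectra
from xlscout.spectra import Ms2Spectrum, Tolerance


@pytest.fixture(scope="session")
def dsso():
    return LINKERS["DSSO"]


@pytest.fixture(scope="session")
def tol10():
    return Tolerance(10.0, "ppm")


def make_spectrum(mzs, intensities=None, scan_id="s1", precursor_mz=1000.0,
                  charge=3):
    mzs = np.asarray(mzs, dtype=float)
    if intensities is None:
        intensities = np.ones_like(mzs)
    return Ms2Spectrum(scan_id=scan_id, precursor_mz=precursor_mz,
                       precursor_charge=charge, peaks_mz=mzs,
                       peaks_intensity=np.asarray(intensities, dtype=float))


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, full-coverage, zero-jitter generator settings."""
    return SimulationParams(seed=11, n_proteins=4, protein_length=200,
                            n_spectra=40, fragment_coverage=1.0,
                            doublet_probability=1.0, noise_peaks=0,
                            fragment_ppm_error=0.0, precursor_ppm_error=0.0)


@pytest.fixture(scope="session")
def clean_dataset(clean_params):
    targets, _ = generate_database(clean_params)
    spectra, truth = generate_spectra(targets, clean_params)
    return targets, spectra, truth
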