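"""Synthetic cross-linking MS2 data generator.

Emulates stepped-collision-energy acquisition of cross-linked tryptic
peptides: each spectrum contains the light/heavy stump doublets of both
peptides, partial b/y fragment ladders with stump variants on site-containing
fragments, log-normal intensities, uniform noise peaks and ppm-scale mass
errors.  Alongside the MGF it emits a ground-truth table, and it can produce a
residue-shuffled entrapment database that shares no tryptic peptide with the
targets, for empirical false-positive measurements.

Everything is driven by one seed; identical parameters and seed reproduce the
output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import (C13_C12, PROTON, AA_MONO, CrosslinkerSpec, DigestionParams,
                   LINKERS, Peptide, digest_database, link_positions)
from .search import FragmentModel, theoretical_fragments
from .spectra import Ms2Spectrum, write_mgf

_ALPHABET = sorted(AA_MONO)


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults describe a small bench-scale study."""

    seed: int = 1
    n_proteins: int = 20
    protein_length: int = 300
    n_spectra: int = 500
    linker: CrosslinkerSpec = field(default_factory=lambda: LINKERS["DSSO"])
    fragment_coverage: float = 0.7  # fraction of theoretical ions planted
    doublet_probability: float = 0.95  # per peptide, both stump peaks
    noise_peaks: int = 50
    intensity_mu: float = 10.0  # log-normal, arbitrary units
    intensity_sigma: float = 1.0
    fragment_ppm_error: float = 5.0
    precursor_ppm_error: float = 2.0
    charge_probs: tuple[tuple[int, float], ...] = ((3, 0.50), (4, 0.35), (5, 0.15))
    isotope_misassign_prob: float = 0.0  # precursor recorded at +1 isotope
    entrapment_factor: int = 4  # entrapment proteins per target protein
    min_peptide_mass: float = 500.0
    max_peptide_mass: float = 3500.0
    digestion: DigestionParams = field(default_factory=lambda: DigestionParams(
        missed_cleavages=2, min_length=5, max_length=30,
        variable_modifications=(), max_variable_mods=0))

    def __post_init__(self) -> None:
        for p in (self.fragment_coverage, self.doublet_probability,
                  self.isotope_misassign_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruthRecord:
    """What was planted into one synthetic spectrum."""

    scan_id: str
    alpha_sequence: str
    beta_sequence: str
    alpha_protein: str
    beta_protein: str
    alpha_site: int  # 1-based within peptide
    beta_site: int
    alpha_residue: int  # 1-based within protein
    beta_residue: int
    alpha_mass: float
    beta_mass: float
    precursor_charge: int
    alpha_doublet_charge: int  # 0 when the doublet was not planted
    beta_doublet_charge: int
    isotope_offset: int

    @property
    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return tuple(sorted(((self.alpha_protein, self.alpha_residue),
                             (self.beta_protein, self.beta_residue))))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    # K boosted so tryptic peptides carry linkable sites; R ensures cleavage.
    weights = np.array([0.10 if a == "K" else 0.06 if a == "R" else 0.84 / 18
                        for a in _ALPHABET])
    weights /= weights.sum()
    return "".join(rng.choice(_ALPHABET, size=length, p=weights))


def _tryptic_set(proteins: dict[str, str], params: DigestionParams) -> set[str]:
    return {p.sequence for p in digest_database(proteins, params)}


def generate_database(params: SimulationParams,
                      ) -> tuple[dict[str, str], dict[str, str]]:
    """Random target proteins plus a residue-shuffled entrapment database.

    Entrapment proteins are shuffled copies of targets, re-shuffled until they
    share no tryptic peptide with any target.
    """
    rng = np.random.default_rng(params.seed)
    targets = {f"TGT_{i + 1:04d}": _random_protein(rng, params.protein_length)
               for i in range(params.n_proteins)}
    target_peps = _tryptic_set(targets, params.digestion)
    entrapment: dict[str, str] = {}
    n_ent = params.n_proteins * params.entrapment_factor
    src = list(targets.values())
    for i in range(n_ent):
        base = list(src[i % len(src)]) if src else []
        for _ in range(50):
            rng.shuffle(base)
            seq = "".join(base)
            ent_peps = _tryptic_set({"x": seq}, params.digestion)
            if not (ent_peps & target_peps):
                break
        entrapment[f"ENT_{i + 1:04d}"] = seq
    return targets, entrapment


def _linkable_pool(proteins: dict[str, str], params: SimulationParams,
                   ) -> list[tuple[Peptide, tuple[int, ...]]]:
    lengths = {acc: len(seq) for acc, seq in proteins.items()}
    pool = []
    for pep in digest_database(proteins, params.digestion):
        if not params.min_peptide_mass <= pep.neutral_mass <= params.max_peptide_mass:
            continue
        sites = link_positions(pep, params.linker, lengths)
        if sites:
            pool.append((pep, tuple(sites)))
    pool.sort(key=lambda t: t[0].sequence)
    return pool


def generate_spectra(targets: dict[str, str], params: SimulationParams,
                     ) -> tuple[list[Ms2Spectrum], list[GroundTruthRecord]]:
    """Synthesize cross-linked MS2 spectra and their ground truth.

    Per spectrum: two distinct linkable tryptic peptides are drawn, the
    precursor is computed exactly from the mass relation, both stump doublets
    are planted with the configured probability, a fraction of the theoretical
    b/y ladder (with stump variants) is planted, noise peaks are added and all
    fragment m/z values are jittered by the ppm error model.
    """
    rng = np.random.default_rng(params.seed + 1)
    pool = _linkable_pool(targets, params)
    if len(pool) < 2:
        raise ValueError("database yields fewer than two linkable peptides")
    linker = params.linker
    charges = [z for z, _ in params.charge_probs]
    charge_p = np.array([p for _, p in params.charge_probs])
    charge_p = charge_p / charge_p.sum()
    model = FragmentModel(charges=(1, 2))

    spectra: list[Ms2Spectrum] = []
    truth: list[GroundTruthRecord] = []
    for i in range(params.n_spectra):
        ia, ib = rng.choice(len(pool), size=2, replace=False)
        (pa, sites_a), (pb, sites_b) = pool[ia], pool[ib]
        site_a = int(rng.choice(sites_a))
        site_b = int(rng.choice(sites_b))
        ma, mb = pa.neutral_mass, pb.neutral_mass
        z = int(rng.choice(charges, p=charge_p))
        precursor_mass = ma + mb + linker.intact_mass
        iso = -1 if rng.random() < params.isotope_misassign_prob else 0
        precursor_mz = (precursor_mass - iso * C13_C12 + z * PROTON) / z
        if params.precursor_ppm_error > 0:
            precursor_mz *= 1.0 + rng.normal(0.0, params.precursor_ppm_error) * 1e-6

        mzs: list[float] = []
        doublet_z = []
        for m in (ma, mb):
            if rng.random() < params.doublet_probability:
                zd = 1 if z <= 2 else int(rng.integers(1, min(2, z - 1) + 1))
                mzs.append((m + linker.light_mass + zd * PROTON) / zd)
                mzs.append((m + linker.heavy_mass + zd * PROTON) / zd)
                doublet_z.append(zd)
            else:
                doublet_z.append(0)
        for pep, site in ((pa, site_a), (pb, site_b)):
            frags, _ = theoretical_fragments(pep, site, linker, model)
            keep = rng.random(len(frags)) < params.fragment_coverage
            mzs.extend(float(f) for f in frags[keep])
        if params.fragment_ppm_error > 0:
            mzs = [m * (1.0 + rng.normal(0.0, params.fragment_ppm_error) * 1e-6)
                   for m in mzs]
        if params.noise_peaks > 0:
            mzs.extend(rng.uniform(100.0, precursor_mz, size=params.noise_peaks))
        intensities = rng.lognormal(params.intensity_mu, params.intensity_sigma,
                                    size=len(mzs))
        scan_id = f"SYN_{i + 1:06d}"
        spectra.append(Ms2Spectrum(
            scan_id=scan_id, precursor_mz=float(precursor_mz), precursor_charge=z,
            peaks_mz=np.array(mzs), peaks_intensity=intensities,
            retention_time=60.0 * (i + 1)))
        acc_a, start_a = pa.protein_locations[0]
        acc_b, start_b = pb.protein_locations[0]
        truth.append(GroundTruthRecord(
            scan_id=scan_id, alpha_sequence=pa.sequence, beta_sequence=pb.sequence,
            alpha_protein=acc_a, beta_protein=acc_b,
            alpha_site=site_a, beta_site=site_b,
            alpha_residue=start_a + site_a - 1, beta_residue=start_b + site_b - 1,
            alpha_mass=ma, beta_mass=mb, precursor_charge=z,
            alpha_doublet_charge=doublet_z[0], beta_doublet_charge=doublet_z[1],
            isotope_offset=iso))
    return spectra, truth


def write_fasta(proteins: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in proteins.items():
            fh.write(f">{acc}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")


def write_truth(truth: list[GroundTruthRecord], path) -> None:
    pd.DataFrame([asdict(t) for t in truth]).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[GroundTruthRecord]:
    df = pd.read_csv(path, sep="\t")
    return [GroundTruthRecord(**{k: row[k] for k in df.columns}) for _, row in
            df.astype({c: int for c in df.columns if c.endswith(
                ("_site", "_residue", "_charge", "_offset"))}).iterrows()]


def simulate_dataset(params: SimulationParams, out_dir) -> dict[str, Path]:
    """Write targets.fasta, entrapment.fasta, spectra.mgf and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets, entrapment = generate_database(params)
    spectra, truth = generate_spectra(targets, params)
    paths = {
        "targets": out / "targets.fasta",
        "entrapment": out / "entrapment.fasta",
        "spectra": out / "spectra.mgf",
        "truth": out / "truth.tsv",
    }
    write_fasta(targets, paths["targets"])
    write_fasta(entrapment, paths["entrapment"])
    write_mgf(spectra, paths["spectra"])
    write_truth(truth, paths["truth"])
    return paths
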