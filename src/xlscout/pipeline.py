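"""End-to-end search pipeline: FASTA + MGF in, validated result tables out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from pyteomics import fasta as _pyt_fasta

from . import __version__
from .chem import (CandidateIndex, DECOY_PREFIX, Peptide, digest_database,
                   make_decoy_database)
from .config import RunConfig
from .detector import PairingStats
from .search import CSM, PeptideHit, search_spectrum
from .spectra import read_mgf
from .validate import validate_all

def read_fasta(path) -> dict[str, str]:
    """Accession (first whitespace-delimited header token) -> sequence."""
    proteins: dict[str, str] = {}
    with _pyt_fasta.read(str(path)) as reader:
        for header, seq in reader:
            proteins[header.split()[0]] = seq.upper()
    return proteins


def build_index(proteins: dict[str, str], config: RunConfig) -> CandidateIndex:
    """Digest targets + reversed decoys into a mass-sorted candidate index."""
    decoys = make_decoy_database(proteins)
    combined = {**proteins, **decoys}
    peptides = digest_database(combined, config.digestion)
    lengths = {acc: len(seq) for acc, seq in combined.items()}
    return CandidateIndex(peptides, config.linker, lengths)


def _locs_str(pep: Peptide) -> str:
    return ";".join(f"{acc}:{start}" for acc, start in pep.protein_locations)


def _mods_str(pep: Peptide) -> str:
    return ";".join(f"{pos}:{shift:.5f}" for pos, shift in pep.modifications)


def csms_to_frame(labeled_csms) -> pd.DataFrame:
    rows = []
    for lc in labeled_csms:
        c = lc.csm
        rows.append({
            "scan_id": c.scan_id,
            "alpha_sequence": c.alpha.peptide.sequence,
            "beta_sequence": c.beta.peptide.sequence,
            "alpha_mods": _mods_str(c.alpha.peptide),
            "beta_mods": _mods_str(c.beta.peptide),
            "alpha_locations": _locs_str(c.alpha.peptide),
            "beta_locations": _locs_str(c.beta.peptide),
            "alpha_link_position": c.alpha.link_position,
            "beta_link_position": c.beta.link_position,
            "alpha_score": c.alpha.score,
            "beta_score": c.beta.score,
            "score": c.score,
            "precursor_error_ppm": c.precursor_error_ppm,
            "precursor_charge": c.precursor_charge,
            "isotope_offset": c.isotope_offset,
            "decoy_class": c.decoy_class,
            "link_class": c.link_class,
            "mode": c.mode,
            "confidence": lc.confidence,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["score", "alpha_sequence", "beta_sequence"],
                            ascending=[False, True, True], kind="stable")
    return df.reset_index(drop=True)


def read_csms_tsv(path) -> list[CSM]:
    """Rebuild CSM objects from a csms.tsv written by :func:`run_search`."""

    def parse_locs(s: str):
        return tuple((part.rsplit(":", 1)[0], int(part.rsplit(":", 1)[1]))
                     for part in str(s).split(";") if part and part != "nan")

    def parse_mods(s):
        if pd.isna(s) or not str(s):
            return ()
        return tuple((int(p.split(":")[0]), float(p.split(":")[1]))
                     for p in str(s).split(";"))

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        hits = {}
        for side in ("alpha", "beta"):
            locs = parse_locs(r[f"{side}_locations"])
            pep = Peptide(r[f"{side}_sequence"], locs, parse_mods(r[f"{side}_mods"]),
                          is_decoy=all(a.startswith(DECOY_PREFIX) for a, _ in locs))
            hits[side] = PeptideHit(pep, int(r[f"{side}_link_position"]),
                                    float(r[f"{side}_score"]), 0, 0, 0.0)
        out.append(CSM(scan_id=str(r["scan_id"]), alpha=hits["alpha"],
                       beta=hits["beta"], score=float(r["score"]),
                       precursor_error_ppm=float(r["precursor_error_ppm"]),
                       decoy_class=str(r["decoy_class"]),
                       link_class=str(r["link_class"]), mode=str(r["mode"]),
                       precursor_charge=int(r["precursor_charge"]),
                       isotope_offset=int(r["isotope_offset"])))
    return out


def crosslinks_to_frame(labeled_links) -> pd.DataFrame:
    rows = []
    for xl in labeled_links:
        (p1, r1), (p2, r2) = xl.residue_pair
        rows.append({
            "protein_1": p1, "residue_1": r1,
            "protein_2": p2, "residue_2": r2,
            "score": xl.score, "n_csms": len(xl.csms),
            "link_class": xl.link_class, "decoy": xl.decoy,
            "confidence": xl.confidence,
            "best_scan_id": xl.csms[0].scan_id,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["score", "protein_1", "residue_1", "protein_2",
                             "residue_2"],
                            ascending=[False, True, True, True, True],
                            kind="stable")
    return df.reset_index(drop=True)


def run_search(spectra_path, fasta_path, config: RunConfig, out_dir,
               stats: PairingStats | None = None) -> dict:
    """Run the full detector -> search -> validator chain and write results.

    Writes ``csms.tsv``, ``crosslinks.tsv`` and ``run.log`` to ``out_dir``.
    Spectra are processed independently of each other and results are sorted
    canonically (descending score, then sequences), so the output does not
    depend on processing order.  Returns a summary dict with the tallies.
    """
    spectra_path, fasta_path = Path(spectra_path), Path(fasta_path)
    if not spectra_path.exists():
        raise FileNotFoundError(f"spectra file not found: {spectra_path}")
    if not fasta_path.exists():
        raise FileNotFoundError(f"FASTA file not found: {fasta_path}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    proteins = read_fasta(fasta_path)
    index = build_index(proteins, config)
    spectra = read_mgf(spectra_path)

    csms: list[CSM] = []
    n_detected = 0
    for s in spectra:
        csm = search_spectrum(s, index, config.linker, config.search, stats=stats)
        if csm is not None:
            n_detected += 1
            csms.append(csm)
    labeled_csms, labeled_links = validate_all(csms, config.fdr)

    df_csms = csms_to_frame(labeled_csms)
    df_links = crosslinks_to_frame(labeled_links)
    if not config.include_decoys_in_output:
        if len(df_csms):
            df_csms = df_csms[df_csms["decoy_class"] == "TT"].reset_index(drop=True)
        if len(df_links):
            df_links = df_links[~df_links["decoy"]].reset_index(drop=True)
    df_csms.to_csv(out / "csms.tsv", sep="\t", index=False)
    df_links.to_csv(out / "crosslinks.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "spectra_read": len(spectra),
        "spectra_with_doublets": n_detected,
        "csms": len(csms),
        "csms_target": sum(1 for c in csms if not c.is_decoy),
        "crosslinks": len(labeled_links),
        "crosslinks_high": sum(1 for x in labeled_links
                               if x.confidence == "high" and not x.decoy),
        "crosslinks_medium_or_better": sum(
            1 for x in labeled_links
            if x.confidence in ("high", "medium") and not x.decoy),
    }
    with open(out / "run.log", "w") as fh:
        fh.write(f"xlscout version {__version__}\n")
        fh.write(f"spectra: {spectra_path}\nfasta: {fasta_path}\n")
        fh.write("[config]\n")
        for k, v in sorted(config.echo().items()):
            fh.write(f"{k} = {v}\n")
        fh.write("[tallies]\n")
        for k, v in summary.items():
            fh.write(f"{k} = {v}\n")
    return summary
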