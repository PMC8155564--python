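"""Monoisotopic mass arithmetic, in-silico digestion, decoys and cross-linker chemistry.

The cleavable cross-linker chemistry is the heart of the method: a symmetric
MS-cleavable linker (DSSO, DSBU, ...) fragments in the collision cell into a
lighter and a heavier "stump", each of which stays attached to one of the two
linked peptides.  The two stump variants of the same peptide therefore appear
as a peak pair ("doublet") separated by ``heavy_mass - light_mass`` per charge,
and ``light_mass + heavy_mass == intact_mass`` for symmetric linkers.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np
from pyteomics import parser as _pyt_parser

# Monoisotopic constants (Da).
PROTON = 1.007276
WATER = 18.0105646863
C13_C12 = 1.0033548

#: Monoisotopic residue masses of the 20 standard amino acids (Da).
AA_MONO: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Common modification mass shifts (Da).
CARBAMIDOMETHYL = 57.02146
OXIDATION = 15.99491

DECOY_PREFIX = "REV_"

_VALID_SEQ = re.compile(r"^[%s]+$" % "".join(AA_MONO))


class InvalidSequenceError(ValueError):
    """Raised for empty sequences or letters outside the 20-residue alphabet."""


def peptide_mass(sequence: str, modifications: dict[int, float] | None = None) -> float:
    """Monoisotopic neutral mass of a peptide: residues + water + modification shifts.

    Parameters
    ----------
    sequence:
        Amino-acid string over the 20 standard one-letter codes.
    modifications:
        Map of 1-based residue position to mass shift in Da.
    """
    if not sequence or not _VALID_SEQ.match(sequence):
        raise InvalidSequenceError(f"invalid peptide sequence: {sequence!r}")
    m = sum(AA_MONO[a] for a in sequence) + WATER
    if modifications:
        m += sum(modifications.values())
    return m


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemistry of an MS-cleavable cross-linker.

    ``intact_mass`` is the residue mass added between the two linked residues;
    ``light_mass``/``heavy_mass`` are the two cleavage-fragment stumps.
    """

    name: str
    intact_mass: float
    light_mass: float
    heavy_mass: float
    reactive_residues: frozenset[str]
    protein_nterm: bool = False
    protein_cterm: bool = False
    diagnostic_ions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.light_mass < self.heavy_mass:
            raise ValueError("light_mass must be smaller than heavy_mass")
        if abs(self.light_mass + self.heavy_mass - self.intact_mass) > 1e-4:
            raise ValueError("stump masses must sum to the intact linker mass")

    @property
    def doublet_delta(self) -> float:
        """Mass difference between the heavy and light stump (Da)."""
        return self.heavy_mass - self.light_mass


#: Built-in linker presets; masses from elemental compositions.
LINKERS: dict[str, CrosslinkerSpec] = {
    "DSSO": CrosslinkerSpec(
        name="DSSO", intact_mass=158.00377, light_mass=54.01057,
        heavy_mass=103.99320, reactive_residues=frozenset("K"),
        diagnostic_ions=(),
    ),
    "DSBU": CrosslinkerSpec(
        name="DSBU", intact_mass=196.08479, light_mass=85.05276,
        heavy_mass=111.03203, reactive_residues=frozenset("K"),
        diagnostic_ions=(),
    ),
}


@dataclass(frozen=True)
class Peptide:
    """A digested peptide with its protein locations and modifications."""

    sequence: str
    protein_locations: tuple[tuple[str, int], ...]  # (accession, 1-based start)
    modifications: tuple[tuple[int, float], ...] = ()  # 1-based position -> shift
    is_decoy: bool = False

    def __post_init__(self) -> None:
        for _, start in self.protein_locations:
            if start < 1:
                raise ValueError("protein locations are 1-based")

    @property
    def neutral_mass(self) -> float:
        return peptide_mass(self.sequence, dict(self.modifications))

    @property
    def mod_map(self) -> dict[int, float]:
        return dict(self.modifications)


@dataclass(frozen=True)
class DigestionParams:
    """Enzymatic digestion settings (default: trypsin, cleave after K/R not before P)."""

    rule: str = r"[KR](?!P)"
    missed_cleavages: int = 2
    min_length: int = 5
    max_length: int = 30
    fixed_modifications: tuple[tuple[str, float], ...] = (("C", CARBAMIDOMETHYL),)
    variable_modifications: tuple[tuple[str, float], ...] = (("M", OXIDATION),)
    max_variable_mods: int = 2

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must not exceed max_length")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


def _expand_modifications(sequence: str, params: DigestionParams):
    """Yield modification maps: fixed mods everywhere, variable mods combinatorially."""
    fixed = {i + 1: shift for i, aa in enumerate(sequence)
             for res, shift in params.fixed_modifications if aa == res}
    var_sites = [(i + 1, shift) for i, aa in enumerate(sequence)
                 for res, shift in params.variable_modifications if aa == res]
    yield dict(fixed)
    for k in range(1, min(params.max_variable_mods, len(var_sites)) + 1):
        for combo in itertools.combinations(var_sites, k):
            mods = dict(fixed)
            mods.update(combo)
            yield mods


def digest(protein_sequence: str, params: DigestionParams = DigestionParams(),
           accession: str = "", is_decoy: bool = False) -> list[Peptide]:
    """Tryptic digest of one protein into :class:`Peptide` objects.

    All cleavage products obeying the rule, the missed-cleavage bound and the
    length bounds are returned, expanded over variable-modification states.
    """
    if not protein_sequence:
        return []
    out: list[Peptide] = []
    for start, pep in _pyt_parser.icleave(
            protein_sequence, params.rule,
            missed_cleavages=params.missed_cleavages, regex=True):
        if not (params.min_length <= len(pep) <= params.max_length):
            continue
        if not _VALID_SEQ.match(pep):
            continue
        loc = ((accession, start + 1),) if accession else ((accession or "?", start + 1),)
        for mods in _expand_modifications(pep, params):
            out.append(Peptide(pep, loc, tuple(sorted(mods.items())), is_decoy))
    return out


def make_decoy_database(proteins: dict[str, str]) -> dict[str, str]:
    """One decoy per target protein by full sequence reversal; accession prefixed ``REV_``."""
    if not proteins:
        raise ValueError("target database is empty")
    return {DECOY_PREFIX + acc: seq[::-1] for acc, seq in proteins.items()}


def digest_database(proteins: dict[str, str], params: DigestionParams = DigestionParams(),
                    ) -> list[Peptide]:
    """Digest a protein database and merge identical peptide/modification states.

    A peptide occurring in both target and decoy proteins is counted as target
    (conservative for FDR).  ``protein_locations`` carries every occurrence.
    """
    merged: dict[tuple[str, tuple], dict] = {}
    for acc, seq in proteins.items():
        is_decoy = acc.startswith(DECOY_PREFIX)
        for pep in digest(seq, params, accession=acc, is_decoy=is_decoy):
            key = (pep.sequence, pep.modifications)
            entry = merged.setdefault(key, {"locs": [], "decoy": True})
            entry["locs"].extend(pep.protein_locations)
            entry["decoy"] = entry["decoy"] and is_decoy
    return [
        Peptide(seq, tuple(sorted(set(e["locs"]))), mods, e["decoy"])
        for (seq, mods), e in sorted(merged.items())
    ]


def link_positions(peptide: Peptide, linker: CrosslinkerSpec,
                   protein_lengths: dict[str, int] | None = None) -> list[int]:
    """1-based residue indices of the peptide where the linker can attach.

    A residue is linkable if it is reactive and not the C-terminal residue of
    the tryptic peptide (a cross-linked K/R cannot be cleaved by trypsin),
    except when the peptide ends at the protein C-terminus.  If the linker is
    protein-N-term reactive, position 1 of a protein N-terminal peptide also
    qualifies.
    """
    seq = peptide.sequence
    n = len(seq)
    at_protein_cterm = False
    if protein_lengths:
        at_protein_cterm = any(
            start + n - 1 == protein_lengths.get(acc, -1)
            for acc, start in peptide.protein_locations)
    positions = []
    for i, aa in enumerate(seq, start=1):
        if aa in linker.reactive_residues and (i < n or at_protein_cterm):
            positions.append(i)
    if linker.protein_nterm and any(s == 1 for _, s in peptide.protein_locations):
        if 1 not in positions:
            positions.insert(0, 1)
    return positions


class CandidateIndex:
    """Mass-sorted index of linkable candidate peptides with range queries."""

    def __init__(self, peptides: list[Peptide], linker: CrosslinkerSpec,
                 protein_lengths: dict[str, int] | None = None):
        entries = []
        for p in peptides:
            sites = link_positions(p, linker, protein_lengths)
            if sites:
                entries.append((p.neutral_mass, p, tuple(sites)))
        entries.sort(key=lambda t: (t[0], t[1].sequence, t[1].modifications))
        self._masses = np.array([m for m, _, _ in entries], dtype=float)
        self._peptides = [p for _, p, _ in entries]
        self._sites = [s for _, _, s in entries]
        self.linker = linker

    def __len__(self) -> int:
        return len(self._peptides)

    @property
    def peptides(self) -> list[Peptide]:
        return list(self._peptides)

    def sites(self, i: int) -> tuple[int, ...]:
        return self._sites[i]

    def query(self, mass: float, tolerance: "Tolerance") -> list[int]:
        """Indices of candidates whose neutral mass is within ``tolerance`` of ``mass``."""
        w = tolerance.window(mass)
        lo = int(np.searchsorted(self._masses, mass - w, side="left"))
        hi = int(np.searchsorted(self._masses, mass + w, side="right"))
        return list(range(lo, hi))

    def mass(self, i: int) -> float:
        return float(self._masses[i])


def linker_from_config(name: str, intact: float, light: float, heavy: float,
                       residues: str, diagnostic: tuple[float, ...] = (),
                       protein_nterm: bool = False) -> CrosslinkerSpec:
    """Build an arbitrary user-defined cleavable linker."""
    return CrosslinkerSpec(name=name, intact_mass=intact, light_mass=light,
                           heavy_mass=heavy, reactive_residues=frozenset(residues),
                           protein_nterm=protein_nterm,
                           diagnostic_ions=tuple(diagnostic))
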