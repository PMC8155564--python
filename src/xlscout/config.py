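"""Run configuration: flat INI-style config files and validated defaults."""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, asdict

from .chem import DigestionParams, CrosslinkerSpec, LINKERS, linker_from_config
from .detector import DetectorConfig
from .search import SearchConfig
from .spectra import Tolerance
from .validate import FdrConfig


@dataclass
class RunConfig:
    """All parameter groups of one search run."""

    digestion: DigestionParams = field(default_factory=DigestionParams)
    linker: CrosslinkerSpec = field(default_factory=lambda: LINKERS["DSSO"])
    search: SearchConfig = field(default_factory=SearchConfig)
    fdr: FdrConfig = field(default_factory=FdrConfig)
    threads: int = 1
    include_decoys_in_output: bool = False

    def echo(self) -> dict:
        """Flat mapping of every effective setting, for the run log."""
        d = {
            "linker.name": self.linker.name,
            "linker.intact_mass": self.linker.intact_mass,
            "linker.light_mass": self.linker.light_mass,
            "linker.heavy_mass": self.linker.heavy_mass,
            "linker.reactive_residues": "".join(sorted(self.linker.reactive_residues)),
            "detector.mode": self.search.detector.mode,
            "detector.doublet_tolerance_ppm": self.search.detector.doublet_tolerance.value,
            "detector.pair_tolerance_ppm": self.search.detector.pair_tolerance.value,
            "detector.max_isotope_offsets": self.search.detector.max_isotope_offsets,
            "search.top_n": self.search.top_n,
            "search.ms2_tolerance_ppm": self.search.ms2_tolerance.value,
            "search.peptide_mass_tolerance_ppm": self.search.peptide_mass_tolerance.value,
            "fdr.csm_thresholds": ",".join(map(str, self.fdr.csm_thresholds)),
            "fdr.crosslink_thresholds": ",".join(map(str, self.fdr.crosslink_thresholds)),
            "fdr.separate_intra_inter": self.fdr.separate_intra_inter,
            "threads": self.threads,
        }
        d.update({f"digestion.{k}": v for k, v in asdict(self.digestion).items()})
        return d


def _get(cp: configparser.ConfigParser, section: str, key: str, cast, default):
    if cp.has_option(section, key):
        raw = cp.get(section, key)
        if cast is bool:
            return raw.strip().lower() in ("1", "true", "yes", "on")
        return cast(raw)
    return default


def load_config(path) -> RunConfig:
    """Parse a flat INI config file into a :class:`RunConfig`."""
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    base = RunConfig()

    dig = DigestionParams(
        missed_cleavages=_get(cp, "digestion", "missed_cleavages", int, 2),
        min_length=_get(cp, "digestion", "min_length", int, 5),
        max_length=_get(cp, "digestion", "max_length", int, 30),
        max_variable_mods=_get(cp, "digestion", "max_variable_mods", int, 2),
    )

    linker = LINKERS.get(_get(cp, "linker", "name", str, "DSSO"))
    if cp.has_option("linker", "intact_mass"):
        linker = linker_from_config(
            name=_get(cp, "linker", "name", str, "custom"),
            intact=cp.getfloat("linker", "intact_mass"),
            light=cp.getfloat("linker", "light_mass"),
            heavy=cp.getfloat("linker", "heavy_mass"),
            residues=_get(cp, "linker", "reactive_residues", str, "K"),
            diagnostic=tuple(
                float(x) for x in
                _get(cp, "linker", "diagnostic_ions", str, "").split(",") if x),
        )
    if linker is None:
        raise ValueError("unknown linker name in config")

    detector = DetectorConfig(
        mode=_get(cp, "detector", "mode", str, "combined"),
        doublet_tolerance=Tolerance(
            _get(cp, "detector", "doublet_tolerance_ppm", float, 10.0), "ppm"),
        pair_tolerance=Tolerance(
            _get(cp, "detector", "pair_tolerance_ppm", float, 5.0), "ppm"),
        max_isotope_offsets=_get(cp, "detector", "max_isotope_offsets", int, 0),
    )
    search = SearchConfig(
        top_n=_get(cp, "search", "top_n", int, 5),
        ms2_tolerance=Tolerance(_get(cp, "search", "ms2_tolerance_ppm", float, 10.0), "ppm"),
        peptide_mass_tolerance=Tolerance(
            _get(cp, "search", "peptide_mass_tolerance_ppm", float, 20.0), "ppm"),
        detector=detector,
    )
    fdr_csm = _get(cp, "fdr", "csm_thresholds", str, "0.01,0.05").split(",")
    fdr_xl = _get(cp, "fdr", "crosslink_thresholds", str, "0.01,0.05").split(",")
    fdr = FdrConfig(
        csm_thresholds=(float(fdr_csm[0]), float(fdr_csm[1])),
        crosslink_thresholds=(float(fdr_xl[0]), float(fdr_xl[1])),
        separate_intra_inter=_get(cp, "fdr", "separate_intra_inter", bool, False),
    )
    return RunConfig(digestion=dig, linker=linker, search=search, fdr=fdr,
                     threads=_get(cp, "output", "threads", int, base.threads))
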