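"""MS2 spectrum container, MGF input/output and peak-matching primitives."""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _pyt_mgf

from .chem import PROTON


@dataclass(frozen=True)
class Tolerance:
    """A mass tolerance, either absolute (Da) or relative (ppm)."""

    value: float
    unit: str = "ppm"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("tolerance must be positive")
        if self.unit not in ("Da", "ppm"):
            raise ValueError("tolerance unit must be 'Da' or 'ppm'")

    def window(self, reference: float) -> float:
        """Half-width of the acceptance window in Da at ``reference`` (m/z or Da)."""
        if self.unit == "Da":
            return self.value
        return self.value * 1e-6 * abs(reference)

    def contains(self, observed: float, expected: float) -> bool:
        return abs(observed - expected) <= self.window(expected)


class MgfParseError(ValueError):
    """Raised when an MGF block cannot be parsed; names the offending scan."""


@dataclass
class Ms2Spectrum:
    """One centroided MS2 scan: precursor descriptor plus a sorted peak list."""

    scan_id: str
    precursor_mz: float
    precursor_charge: int | None
    peaks_mz: np.ndarray
    peaks_intensity: np.ndarray
    retention_time: float | None = None
    ion_mobility: float | None = None  # 1/K0, pass-through only
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.peaks_intensity = np.asarray(self.peaks_intensity, dtype=float)
        order = np.argsort(self.peaks_mz, kind="stable")
        self.peaks_mz = self.peaks_mz[order]
        self.peaks_intensity = self.peaks_intensity[order]

    def __len__(self) -> int:
        return len(self.peaks_mz)

    @property
    def charge_known(self) -> bool:
        return self.precursor_charge is not None and self.precursor_charge >= 1

    def precursor_neutral_mass(self, charge: int | None = None) -> float:
        """Uncharged precursor mass at the recorded (or an assumed) charge."""
        z = charge if charge is not None else self.precursor_charge
        if z is None or z < 1:
            raise ValueError(f"spectrum {self.scan_id}: precursor charge unknown")
        return self.precursor_mz * z - z * PROTON

    def total_intensity(self) -> float:
        return float(self.peaks_intensity.sum())


def read_mgf(path) -> list[Ms2Spectrum]:
    """Read an MGF file into a list of :class:`Ms2Spectrum`.

    One spectrum per BEGIN/END IONS block.  The first PEPMASS value is the
    precursor m/z; CHARGE is parsed with its sign; RTINSECONDS and
    ION_MOBILITY are picked up when present and all other headers are kept in
    ``metadata``.  Spectra without a CHARGE line get ``precursor_charge=None``
    and are subject to charge enumeration downstream.
    """
    spectra: list[Ms2Spectrum] = []
    try:
        with _pyt_mgf.MGF(str(path), convert_arrays=1) as reader:
            for entry in reader:
                params = dict(entry["params"])
                title = str(params.pop("title", f"scan_{len(spectra) + 1}"))
                try:
                    pepmass = params.pop("pepmass")
                    mz = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
                except (KeyError, TypeError, ValueError) as exc:
                    raise MgfParseError(f"scan {title!r}: bad or missing PEPMASS") from exc
                charge = None
                if "charge" in params:
                    ch = params.pop("charge")
                    charge = int(ch[0]) if isinstance(ch, (tuple, list)) else int(ch)
                rt = params.pop("rtinseconds", None)
                rt = float(rt) if rt is not None else None
                im = params.pop("ion_mobility", None)
                im = float(im) if im is not None else None
                spectra.append(Ms2Spectrum(
                    scan_id=title, precursor_mz=mz, precursor_charge=charge,
                    peaks_mz=entry["m/z array"], peaks_intensity=entry["intensity array"],
                    retention_time=rt, ion_mobility=im, metadata=params))
    except MgfParseError:
        raise
    except Exception as exc:  # malformed block
        raise MgfParseError(f"malformed MGF block near spectrum "
                            f"{len(spectra) + 1}: {exc}") from exc
    return spectra


def write_mgf(spectra: list[Ms2Spectrum], path) -> None:
    """Write spectra to MGF; keys emitted as TITLE, PEPMASS, CHARGE, then optionals."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.precursor_charge is not None:
                sign = "+" if s.precursor_charge > 0 else "-"
                fh.write(f"CHARGE={abs(s.precursor_charge)}{sign}\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time:.3f}\n")
            if s.ion_mobility is not None:
                fh.write(f"ION_MOBILITY={s.ion_mobility:.4f}\n")
            for mz, it in zip(s.peaks_mz, s.peaks_intensity):
                fh.write(f"{mz:.6f} {it:.6f}\n")
            fh.write("END IONS\n")


def match_peak(spectrum: Ms2Spectrum, target_mz: float,
               tolerance: Tolerance) -> int | None:
    """Index of the peak best matching ``target_mz`` within ``tolerance``, or None.

    Ties on |Δm/z| (to 1e-9) are broken toward the more intense peak.
    """
    mz = spectrum.peaks_mz
    if len(mz) == 0:
        return None
    w = tolerance.window(target_mz)
    lo = bisect.bisect_left(mz, target_mz - w)
    hi = bisect.bisect_right(mz, target_mz + w)
    if lo >= hi:
        return None
    best = None
    best_key = None
    for i in range(lo, hi):
        key = (round(abs(mz[i] - target_mz), 9), -spectrum.peaks_intensity[i])
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best
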