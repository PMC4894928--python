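"""Stick-spectrum and chromatogram data model.

Unit-mass (integer Da) centroided EI spectra are the universal currency of
this package: every library entry, every chromatogram scan and every averaged
peak spectrum is a :class:`StickSpectrum`.  Quadrupole EI data is unit
resolution, so any higher-resolution input is binned by rounding each m/z to
the nearest integer and summing intensities.

The similarity measure is a weighted cosine ("dot product") score on the
0-100 scale used by vendor library-search software, with per-peak weights
``w = mz**p * intensity**q`` (defaults ``p = 1.3``, ``q = 0.53``, the
weighting commonly used for EI identity searches).  Vendor formulas are
proprietary; the weighted cosine is a reproducible, monotone surrogate that
preserves the 0-100 scale semantics (100 = identical, 0 = disjoint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PyropigError",
    "EmptySpectrumError",
    "NoOverlapDomainError",
    "FormulaParseError",
    "TooFewScansError",
    "EmptyChromatogramError",
    "StickSpectrum",
    "Scan",
    "Chromatogram",
    "MassWindow",
    "normalize",
    "restrict",
    "match_score",
    "average_mass_spectrum",
    "nominal_mass",
    "NOMINAL_MASSES",
    "DEFAULT_BLEED_MZ",
    "read_msp",
    "write_msp",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class PyropigError(Exception):
    """Base error; ``code`` is a stable machine-readable identifier."""

    code = "error"


class EmptySpectrumError(PyropigError):
    code = "empty-spectrum"


class NoOverlapDomainError(PyropigError):
    """Raised when a spectrum is empty after restriction to the search window.

    Distinct from a score of 0, which means both spectra survived restriction
    but share no m/z.
    """

    code = "no-overlap-domain"


class FormulaParseError(PyropigError):
    code = "formula-parse"


class TooFewScansError(PyropigError):
    code = "too-few-scans"


class EmptyChromatogramError(PyropigError):
    code = "empty-chromatogram"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StickSpectrum:
    """Unit-mass centroided EI spectrum.

    Parameters
    ----------
    peaks
        Ordered ``(mz, intensity)`` pairs; m/z strictly increasing integers
        >= 1, intensities nonnegative.
    metadata
        Free-form key/value pairs (name, formula, source, ...).
    """

    peaks: tuple[tuple[int, float], ...]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev = 0
        for mz, inten in self.peaks:
            if not isinstance(mz, (int, np.integer)) or mz < 1:
                raise ValueError(f"m/z must be an integer >= 1, got {mz!r}")
            if mz <= prev:
                raise ValueError("m/z values must be strictly increasing")
            if inten < 0 or not math.isfinite(inten):
                raise ValueError(f"intensity must be finite and >= 0 at m/z {mz}")
            prev = mz

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[float, float]],
                   metadata: Mapping[str, str] | None = None) -> "StickSpectrum":
        """Build from arbitrary (possibly unsorted, non-integer) pairs.

        m/z values are rounded to the nearest integer and intensities of
        coinciding bins summed (unit-mass binning).
        """
        binned: dict[int, float] = {}
        for mz, inten in pairs:
            key = int(round(float(mz)))
            binned[key] = binned.get(key, 0.0) + float(inten)
        peaks = tuple((mz, binned[mz]) for mz in sorted(binned))
        return cls(peaks=peaks, metadata=dict(metadata or {}))

    @classmethod
    def from_dict(cls, d: Mapping[int, float],
                  metadata: Mapping[str, str] | None = None) -> "StickSpectrum":
        return cls.from_pairs(d.items(), metadata)

    def to_dict(self) -> dict[int, float]:
        return {mz: inten for mz, inten in self.peaks}

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks], dtype=int)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks], dtype=float)

    @property
    def tic(self) -> float:
        """Summed intensity (total ion current contribution of this scan)."""
        return float(sum(p[1] for p in self.peaks))

    @property
    def base_peak(self) -> int:
        if not self.peaks:
            raise EmptySpectrumError("empty spectrum has no base peak")
        return max(self.peaks, key=lambda p: p[1])[0]

    def __len__(self) -> int:
        return len(self.peaks)

    def intensity_at(self, mz: int) -> float:
        for m, i in self.peaks:
            if m == mz:
                return i
        return 0.0


@dataclass(frozen=True)
class Scan:
    """One mass-spectral scan at retention time ``rt`` (seconds)."""

    rt: float
    spectrum: StickSpectrum

    def __post_init__(self) -> None:
        if not math.isfinite(self.rt) or self.rt < 0:
            raise ValueError(f"rt must be finite and >= 0, got {self.rt}")


@dataclass(frozen=True)
class Chromatogram:
    """Time-ordered scans with run metadata.

    Metadata typically carries the pyrolysis temperature (degrees C), the
    sample label and the declared pigment list; instrument method settings
    are metadata only and never computed on.
    """

    scans: tuple[Scan, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=float)

    @property
    def tic(self) -> np.ndarray:
        """Per-scan total ion current."""
        return np.array([s.spectrum.tic for s in self.scans], dtype=float)

    @property
    def total_area(self) -> float:
        """Total chromatogram area: sum of TIC over scans (rectangle rule)."""
        return float(self.tic.sum())

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class MassWindow:
    """Inclusive m/z search window with an excluded-mass set.

    The default analysis window is 30-400 Da with the canonical siloxane
    column-bleed ions excluded; excluded masses outside the window are
    simply ignored.
    """

    lo: int = 30
    hi: int = 400
    excluded: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.lo <= self.hi):
            raise ValueError(f"need 1 <= lo <= hi, got [{self.lo}, {self.hi}]")
        object.__setattr__(self, "excluded", frozenset(self.excluded))

    def contains(self, mz: int) -> bool:
        return self.lo <= mz <= self.hi and mz not in self.excluded

    @classmethod
    def open(cls) -> "MassWindow":
        """A window passing every m/z (identity restriction)."""
        return cls(lo=1, hi=10**6)


#: Canonical siloxane column-bleed ions excluded from AMS searches.
DEFAULT_BLEED_MZ = frozenset({73, 147, 207, 281, 355})


def default_ams_window() -> MassWindow:
    """The 30-400 Da screening window with bleed ions excluded."""
    return MassWindow(lo=30, hi=400, excluded=DEFAULT_BLEED_MZ)


# ---------------------------------------------------------------------------
# Spectrum operations
# ---------------------------------------------------------------------------

def normalize(spec: StickSpectrum) -> StickSpectrum:
    """Scale intensities so the base peak equals 100 (base-peak convention)."""
    if not spec.peaks:
        raise EmptySpectrumError("cannot normalize an empty spectrum")
    top = max(p[1] for p in spec.peaks)
    if top <= 0:
        raise EmptySpectrumError("cannot normalize an all-zero spectrum")
    scale = 100.0 / top
    peaks = tuple((mz, inten * scale) for mz, inten in spec.peaks)
    return StickSpectrum(peaks=peaks, metadata=spec.metadata)


def restrict(spec: StickSpectrum, window: MassWindow) -> StickSpectrum:
    """Drop peaks outside the window or in its excluded set.

    Remaining intensities are unchanged; re-normalization is the caller's
    choice.  May return an empty spectrum.  Idempotent for a fixed window.
    """
    peaks = tuple((mz, i) for mz, i in spec.peaks if window.contains(mz))
    return StickSpectrum(peaks=peaks, metadata=spec.metadata)


def _weighted_vector(spec: StickSpectrum, mz_union: np.ndarray,
                     p: float, q: float) -> np.ndarray:
    d = spec.to_dict()
    inten = np.array([d.get(int(mz), 0.0) for mz in mz_union], dtype=float)
    with np.errstate(divide="ignore"):
        w = np.power(mz_union.astype(float), p) * np.power(inten, q,
                                                           where=inten > 0,
                                                           out=np.zeros_like(inten))
    w[inten <= 0] = 0.0
    return w


def match_score(query: StickSpectrum, ref: StickSpectrum,
                window: MassWindow | None = None,
                p: float = 1.3, q: float = 0.53) -> float:
    """Weighted-cosine similarity on the 0-100 library-search scale.

    Both spectra are restricted to ``window``, normalized, aligned on the
    union of their m/z bins and compared by cosine similarity of the weight
    vectors ``w(mz, I) = mz**p * I**q``.  Symmetric in its arguments and
    invariant under uniform intensity scaling of either spectrum; 100 iff
    the restricted normalized spectra are identical, 0 iff they share no
    m/z.

    Raises
    ------
    NoOverlapDomainError
        If either spectrum is empty after restriction (no common search
        domain exists) -- deliberately distinct from a score of 0.
    """
    window = window or MassWindow.open()
    a = restrict(query, window)
    b = restrict(ref, window)
    if not a.peaks or a.tic == 0 or not b.peaks or b.tic == 0:
        raise NoOverlapDomainError(
            "spectrum empty after restriction to the search window")
    a = normalize(a)
    b = normalize(b)
    union = np.union1d(a.mz, b.mz)
    va = _weighted_vector(a, union, p, q)
    vb = _weighted_vector(b, union, p, q)
    denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
    if denom == 0:
        return 0.0
    cos = float(np.dot(va, vb)) / denom
    # Clip float fuzz so identical spectra score exactly 100.
    return max(0.0, min(1.0, cos)) * 100.0


def average_mass_spectrum(chrom: Chromatogram,
                          window: MassWindow | None = None,
                          rt_range: tuple[float, float] | None = None
                          ) -> StickSpectrum:
    """Whole-run average mass spectrum (AMS).

    For each m/z inside the window (and not excluded), the AMS intensity is
    the sum of that m/z's intensity over all scans; the result is normalized
    to base peak 100.  ``rt_range`` optionally limits the summation, e.g. to
    exclude a solvent-drying phase.  Depends only on the multiset of scans,
    not their order.
    """
    window = window or default_ams_window()
    sums: dict[int, float] = {}
    for scan in chrom.scans:
        if rt_range is not None and not (rt_range[0] <= scan.rt <= rt_range[1]):
            continue
        for mz, inten in scan.spectrum.peaks:
            if window.contains(mz):
                sums[mz] = sums.get(mz, 0.0) + inten
    total = sum(sums.values())
    if not sums or total <= 0:
        raise EmptySpectrumError("chromatogram has no signal inside the window")
    meta = dict(chrom.metadata)
    meta["source"] = "average-mass-spectrum"
    return normalize(StickSpectrum.from_dict(sums, metadata={
        k: str(v) for k, v in meta.items()}))


# ---------------------------------------------------------------------------
# Nominal mass
# ---------------------------------------------------------------------------

#: Integer nominal masses (most abundant isotope) of the elements occurring
#: in pigment pyrolysis products.
NOMINAL_MASSES: dict[str, int] = {
    "H": 1, "B": 11, "C": 12, "N": 14, "O": 16, "F": 19, "Na": 23,
    "Al": 27, "Si": 28, "P": 31, "S": 32, "Cl": 35, "K": 39, "Ca": 40,
    "Ti": 48, "Cr": 52, "Fe": 56, "Ni": 58, "Cu": 63, "Zn": 64,
    "Br": 79, "I": 127, "Ba": 138,
}


def _tokenize_formula(formula: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(formula)
    while i < n:
        ch = formula[i]
        if not ch.isalpha() or not ch.isupper():
            raise FormulaParseError(
                f"malformed formula {formula!r} at position {i}")
        sym = ch
        i += 1
        if i < n and formula[i].islower():
            sym += formula[i]
            i += 1
        count_str = ""
        while i < n and formula[i].isdigit():
            count_str += formula[i]
            i += 1
        if count_str == "":
            count = 1
        else:
            count = int(count_str)
            if count == 0:
                raise FormulaParseError(
                    f"zero count for {sym} in formula {formula!r}")
        tokens.append((sym, count))
    if not tokens:
        raise FormulaParseError("empty formula")
    return tokens


def nominal_mass(formula: str) -> int:
    """Integer nominal mass of a molecular formula such as ``"C8H8"``.

    Sum over elements of count times the nominal mass of the most abundant
    isotope.  Raises :class:`FormulaParseError` for unknown element symbols
    or malformed counts.
    """
    total = 0
    for sym, count in _tokenize_formula(formula):
        if sym not in NOMINAL_MASSES:
            raise FormulaParseError(f"unknown element {sym!r} in {formula!r}")
        total += NOMINAL_MASSES[sym] * count
    return total


# ---------------------------------------------------------------------------
# MSP (NIST text) reader/writer
# ---------------------------------------------------------------------------

def write_msp(spectra: Sequence[StickSpectrum]) -> str:
    """Serialize spectra to NIST MSP text.

    Emits ``Name:``, optional ``Formula:``, any further metadata keys,
    ``Num Peaks:`` and ``mz intensity;`` peak lines.  Integer intensities
    are written without a decimal point so integer data round-trips
    bit-exactly.
    """
    blocks = []
    for spec in spectra:
        meta = dict(spec.metadata)
        lines = [f"Name: {meta.pop('name', 'unknown')}"]
        if "formula" in meta:
            lines.append(f"Formula: {meta.pop('formula')}")
        for key, val in meta.items():
            lines.append(f"{key.capitalize()}: {val}")
        lines.append(f"Num Peaks: {len(spec.peaks)}")
        for mz, inten in spec.peaks:
            if float(inten).is_integer():
                lines.append(f"{mz} {int(inten)};")
            else:
                lines.append(f"{mz} {inten!r};")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def read_msp(text: str) -> list[StickSpectrum]:
    """Parse NIST MSP text into stick spectra (inverse of :func:`write_msp`)."""
    spectra: list[StickSpectrum] = []
    meta: dict[str, str] = {}
    pairs: list[tuple[int, float]] = []
    expected = 0

    def flush() -> None:
        nonlocal meta, pairs, expected
        if meta or pairs:
            if expected and len(pairs) != expected:
                raise ValueError(
                    f"MSP block {meta.get('name', '?')!r}: declared "
                    f"{expected} peaks, found {len(pairs)}")
            spectra.append(StickSpectrum.from_pairs(pairs, metadata=meta))
        meta, pairs, expected = {}, [], 0

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if ":" in line and not line[0].isdigit():
            key, _, val = line.partition(":")
            key = key.strip().lower()
            if key == "name" and (meta or pairs):
                flush()
            if key == "num peaks":
                expected = int(val)
            else:
                meta[key] = val.strip()
        else:
            # peak lines are "mz intensity;", possibly several pairs per line
            fields = line.replace(";", " ").split()
            for mz_s, in_s in zip(fields[0::2], fields[1::2]):
                pairs.append((int(mz_s), float(in_s)))
    flush()
    return spectra


# ---------------------------------------------------------------------------
# Chromatogram CSV (long format: rt,mz,intensity)
# ---------------------------------------------------------------------------

def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    import pandas as pd

    rows = [(s.rt, mz, inten)
            for s in chrom.scans for mz, inten in s.spectrum.peaks]
    df = pd.DataFrame(rows, columns=["rt", "mz", "intensity"])
    df.to_csv(path, index=False)


def read_chromatogram_csv(path, metadata: Mapping[str, object] | None = None
                          ) -> Chromatogram:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"rt", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"chromatogram CSV needs columns {sorted(required)}")
    scans = []
    for rt, grp in df.groupby("rt", sort=True):
        spec = StickSpectrum.from_pairs(
            zip(grp["mz"].tolist(), grp["intensity"].tolist()))
        scans.append(Scan(rt=float(rt), spectrum=spec))
    return Chromatogram(scans=tuple(scans), metadata=dict(metadata or {}))
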