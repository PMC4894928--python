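"""Peak detection, integration and relative-area filtering on pyrograms.

Integration is per-scan summation (rectangle rule on scan index): synthetic
scans are evenly spaced and nothing downstream needs sub-scan accuracy.
Co-eluting components are deliberately *not* deconvolved -- overlapping
peaks merge into one whose spectrum is the mixture, reproducing a real
failure mode the identification layer has to tolerate.  Relative areas are
fractions of the *total chromatogram area* (all scans), not of the sum of
detected peak areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectra import (
    Chromatogram,
    EmptyChromatogramError,
    StickSpectrum,
    TooFewScansError,
    normalize,
)

__all__ = [
    "ChromPeak",
    "detect_peaks",
    "filter_by_relative_area",
    "extracted_ion_fraction",
]


@dataclass(frozen=True)
class ChromPeak:
    """An integrated chromatographic peak.

    ``area`` is the summed TIC over the integration range; ``rel_area`` its
    fraction of the total chromatogram area; ``spectrum`` the scan-averaged,
    base-peak-normalized spectrum over the range (apex-only spectra are
    available via ``detect_peaks(..., spectrum_mode="apex")``).
    """

    rt_apex: float
    rt_start: float
    rt_end: float
    area: float
    rel_area: float
    spectrum: StickSpectrum

    def __post_init__(self) -> None:
        if not (self.rt_start <= self.rt_apex <= self.rt_end):
            raise ValueError("need rt_start <= rt_apex <= rt_end")
        if self.area <= 0:
            raise ValueError("peak area must be > 0")
        if not (0 < self.rel_area <= 1):
            raise ValueError("rel_area must be in (0, 1]")


def _bounds(tic: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk from the apex to the nearest flanking local minima."""
    lo = apex
    while lo > 0 and tic[lo - 1] < tic[lo]:
        lo -= 1
    hi = apex
    while hi < len(tic) - 1 and tic[hi + 1] < tic[hi]:
        hi += 1
    return lo, hi


def _median_background(chrom: Chromatogram) -> dict[int, float]:
    """Per-m/z median intensity across all scans (zeros included).

    Ions present in most scans at a constant level -- column bleed, a
    constant baseline offset -- get their level; genuine peak ions, present
    in only a few scans, get a median of 0 and are left untouched.
    """
    n = len(chrom)
    values: dict[int, list[float]] = {}
    for scan in chrom.scans:
        for mz, inten in scan.spectrum.peaks:
            values.setdefault(mz, []).append(inten)
    background: dict[int, float] = {}
    for mz, vals in values.items():
        if len(vals) <= n // 2:
            continue  # absent from >= half the scans: median is 0
        padded = vals + [0.0] * (n - len(vals))
        background[mz] = float(np.median(padded))
    return background


def _region_spectrum(chrom: Chromatogram, lo: int, hi: int,
                     weights: np.ndarray,
                     background: dict[int, float]) -> StickSpectrum:
    sums: dict[int, float] = {}
    for idx in range(lo, hi + 1):
        w = weights[idx - lo]
        if w == 0:
            continue
        for mz, inten in chrom.scans[idx].spectrum.peaks:
            sums[mz] = sums.get(mz, 0.0) + w * (inten - background.get(mz, 0.0))
    cleaned = {mz: v for mz, v in sums.items() if v > 0}
    if not cleaned:  # peak indistinguishable from background; report raw
        cleaned = {mz: v for mz, v in sums.items() if v != 0}
    return normalize(StickSpectrum.from_dict(cleaned))


def detect_peaks(chrom: Chromatogram, min_prominence: float = 0.01,
                 spectrum_mode: str = "averaged",
                 subtract_background: bool = True) -> list[ChromPeak]:
    """Detect TIC peaks and integrate them.

    Local TIC maxima with prominence above ``min_prominence`` times the
    maximum TIC are kept; each peak's integration range runs to the nearest
    flanking local minima.  A valley scan shared by two adjacent peaks
    contributes half its TIC to each, so the summed relative areas never
    exceed 1.  Deterministic; peaks are returned ordered by apex rt.

    ``spectrum_mode`` selects the reported peak spectrum: ``"averaged"``
    (scan-averaged over the whole range, the default) or ``"apex"`` (the
    apex scan only, emulating apex-pick library searching).  With
    ``subtract_background`` (default) the per-m/z median over all scans --
    the constant column-bleed/baseline level -- is subtracted from peak
    spectra before averaging, the usual background correction ahead of a
    library search; integrated areas are always computed on the raw TIC.
    """
    if len(chrom) < 3:
        raise TooFewScansError("peak detection needs at least 3 scans")
    if spectrum_mode not in ("averaged", "apex"):
        raise ValueError(f"unknown spectrum_mode {spectrum_mode!r}")
    tic = chrom.tic
    top = float(tic.max())
    if top <= 0:
        return []
    apexes, _ = find_peaks(tic, prominence=min_prominence * top)
    total = chrom.total_area
    background = _median_background(chrom) if subtract_background else {}
    regions = [(_bounds(tic, int(a)) + (int(a),)) for a in apexes]
    out: list[ChromPeak] = []
    for k, (lo, hi, apex) in enumerate(regions):
        weights = np.ones(hi - lo + 1, dtype=float)
        if k > 0 and regions[k - 1][1] == lo:
            weights[0] = 0.5  # valley scan shared with the previous peak
        if k + 1 < len(regions) and regions[k + 1][0] == hi:
            weights[-1] = 0.5  # valley scan shared with the next peak
        area = float((tic[lo:hi + 1] * weights).sum())
        if area <= 0:
            continue
        if spectrum_mode == "apex":
            spec = _region_spectrum(chrom, apex, apex, np.ones(1), background)
        else:
            spec = _region_spectrum(chrom, lo, hi, weights, background)
        out.append(ChromPeak(
            rt_apex=float(chrom.scans[apex].rt),
            rt_start=float(chrom.scans[lo].rt),
            rt_end=float(chrom.scans[hi].rt),
            area=area,
            rel_area=area / total,
            spectrum=spec,
        ))
    return out


def filter_by_relative_area(peaks: list[ChromPeak],
                            min_frac: float = 0.002) -> list[ChromPeak]:
    """Keep peaks whose relative area is >= ``min_frac`` (inclusive).

    The default 0.002 keeps every peak carrying at least 0.2 % of the total
    chromatogram area.  Idempotent; monotone in ``min_frac``.
    """
    return [p for p in peaks if p.rel_area >= min_frac]


def extracted_ion_fraction(chrom: Chromatogram, mz: int) -> float:
    """Extracted-ion area of ``mz`` as a fraction of the total area.

    (sum over scans of the intensity at ``mz``) / (total chromatogram
    area); summing this over all m/z present gives exactly 1.
    """
    total = chrom.total_area
    if total <= 0:
        raise EmptyChromatogramError("total chromatogram area is zero")
    eic = sum(s.spectrum.intensity_at(mz) for s in chrom.scans)
    return float(eic) / total
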