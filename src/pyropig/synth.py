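"""Synthetic pyrogram generator.

Emulates the statistical structure of centroided pyrolysis GC/MS runs so
every analysis stage is testable without instrument data: each library
fragment of each formulation component contributes a Gaussian TIC peak at a
fragment-specific reference retention time, the scans under the peak carry
the fragment's reference EI spectrum scaled to the TIC envelope,
multiplicative lognormal noise perturbs every stick, and constant siloxane
column-bleed ions run through every scan.

Reference retention times are synthetic library metadata, ordered by
nominal mass as a volatility proxy -- identification is spectrum-driven,
so retention times only shape co-elution stress tests.

Fragment yield versus pyrolysis temperature follows a logistic onset curve
per chemical class (azo pigments start cleaving around 200 degrees C; very
stable phthalocyanines and quinacridones need upward of 600-800).
Fragments tagged ``impurity`` instead stay constant up to 600 degrees C and
decline above, the behaviour of co-extracted impurities that are consumed,
not formed, at high temperature.  The curves target the qualitative onsets
only, never absolute instrument responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .library import PyroLibrary
from .spectra import Chromatogram, PyropigError, Scan, StickSpectrum

__all__ = [
    "UnknownComponentError",
    "Formulation",
    "SimConfig",
    "GroundTruth",
    "simulate_pyrogram",
    "simulate_temperature_series",
    "reference_rts",
    "temperature_yield",
]


class UnknownComponentError(PyropigError):
    code = "unknown-component"


@dataclass(frozen=True)
class Formulation:
    """Pigment/polymer weight fractions of a simulated ink."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for cid, frac in self.components:
            if frac <= 0:
                raise ValueError(f"component {cid!r}: fraction must be > 0")
            total += frac
        if total > 1 + 1e-9:
            raise ValueError("component fractions must sum to <= 1")

    @classmethod
    def equal_parts(cls, *ids: str) -> "Formulation":
        """Equal-weight suspension of the given components."""
        frac = 1.0 / len(ids)
        return cls(tuple((i, frac) for i in ids))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    pyrolysis_T: float = 800.0      # degrees C
    n_scans: int = 600
    rt_start: float = 60.0          # seconds
    rt_end: float = 1860.0
    peak_width: float = 2.0         # Gaussian sigma, in scans
    noise_sd: float = 0.05          # lognormal sigma on stick intensities
    baseline: float = 0.0           # constant TIC offset spread over bleed ions
    bleed_intensity: float = 0.1    # per bleed ion per scan
    coelution_jitter: float = 0.5   # rt jitter sigma, in scans
    intensity_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_scans < 10:
            raise ValueError("need at least 10 scans")
        for name in ("peak_width", "noise_sd", "baseline", "bleed_intensity",
                     "coelution_jitter", "intensity_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rt_end <= self.rt_start:
            raise ValueError("rt_end must exceed rt_start")


@dataclass(frozen=True)
class GroundTruth:
    """Programmed (pre-noise) signal bookkeeping of one simulated run."""

    #: (component id, fragment name) -> realized TIC area (sum over scans)
    areas: dict[tuple[str, str], float] = field(default_factory=dict)
    #: fragment name -> apex scan index
    apex_scan: dict[str, int] = field(default_factory=dict)
    total_area: float = 0.0

    def fragment_area(self, fragment: str) -> float:
        return sum(a for (_, f), a in self.areas.items() if f == fragment)

    def component_area(self, cid: str) -> float:
        return sum(a for (c, _), a in self.areas.items() if c == cid)


BLEED_IONS = (73, 147, 207, 281, 355)

#: Logistic onset (midpoint degrees C, slope degrees C) per chemical class.
CLASS_ONSET: dict[str, tuple[float, float]] = {
    "azo": (300.0, 60.0),
    "diazo": (300.0, 60.0),
    "phthalocyanine": (750.0, 50.0),
    "quinacridone": (750.0, 50.0),
    "quinophthalone": (550.0, 80.0),
    "diketopyrrolopyrrole": (500.0, 70.0),
    "triphendioxazine": (500.0, 70.0),
    "polycyclic-other": (600.0, 70.0),
    "polymer": (400.0, 60.0),
    "additive": (400.0, 60.0),
}


def temperature_yield(chem_class: str, temp: float, impurity: bool = False
                      ) -> float:
    """Relative fragment yield at a pyrolysis temperature.

    Decomposition products follow a class-specific logistic onset;
    ``impurity``-tagged species are constant up to 600 degrees C and decay
    exponentially above.
    """
    if impurity:
        return 1.0 if temp <= 600 else math.exp(-(temp - 600.0) / 200.0)
    mid, slope = CLASS_ONSET[chem_class]
    return 1.0 / (1.0 + math.exp((mid - temp) / slope))


def reference_rts(library: PyroLibrary, cfg: SimConfig) -> dict[str, int]:
    """Fragment name -> reference apex scan index.

    Fragments are spread evenly over the usable scan range in order of
    (nominal mass, name): nominal mass stands in for volatility.  Stable
    across runs for a fixed library and scan count.
    """
    names = sorted(library.fragments,
                   key=lambda n: (library.fragments[n].nominal_mz, n))
    margin = max(4, int(4 * cfg.peak_width))
    usable = cfg.n_scans - 2 * margin
    if usable < len(names):
        raise ValueError("too few scans to place all library fragments")
    return {name: margin + int(round(i * usable / max(1, len(names) - 1)))
            for i, name in enumerate(names)}


def simulate_pyrogram(formulation: Formulation, library: PyroLibrary,
                      cfg: SimConfig) -> tuple[Chromatogram, GroundTruth]:
    """Simulate one pyrogram; deterministic for a fixed seed.

    Peak height of a fragment is component weight x fragment relative yield
    x class temperature-yield factor x ``intensity_scale``.  The Gaussian
    envelope is truncated at 4 sigma.  Ground truth records exact
    programmed (pre-noise, pre-bleed) areas per (component, fragment).
    """
    for cid, _ in formulation.components:
        if cid not in library.pigments:
            raise UnknownComponentError(f"unknown component {cid!r}")
    rng = np.random.default_rng(cfg.seed)
    rts = reference_rts(library, cfg)
    n = cfg.n_scans
    grid = np.zeros((n, 0))
    signal: list[dict[int, float]] = [dict() for _ in range(n)]
    truth = GroundTruth()

    half = int(math.ceil(4 * cfg.peak_width))
    for cid, weight in formulation.components:
        chem_class = library.pigments[cid].chem_class
        for fname, rel_yield in sorted(library.fragments_of(cid).items()):
            rec = library.fragments[fname]
            impurity = "impurity" in rec.tags
            height = (weight * rel_yield * cfg.intensity_scale *
                      temperature_yield(chem_class, cfg.pyrolysis_T, impurity))
            if height <= 0:
                continue
            center = rts[fname]
            if cfg.coelution_jitter > 0:
                center += rng.normal(0.0, cfg.coelution_jitter)
            center = min(max(center, half), n - 1 - half)
            ref = rec.spectrum
            ref_tic = ref.tic
            area = 0.0
            apex = int(round(center))
            for idx in range(max(0, apex - half), min(n, apex + half + 1)):
                env = height * math.exp(-0.5 * ((idx - center) /
                                                cfg.peak_width) ** 2)
                if env <= 0:
                    continue
                area += env
                scale = env / ref_tic
                bucket = signal[idx]
                for mz, inten in ref.peaks:
                    bucket[mz] = bucket.get(mz, 0.0) + scale * inten
            key = (cid, fname)
            truth.areas[key] = truth.areas.get(key, 0.0) + area
            truth.apex_scan[fname] = apex
    del grid

    rt_axis = np.linspace(cfg.rt_start, cfg.rt_end, n)
    scans = []
    per_ion_baseline = cfg.baseline / len(BLEED_IONS) if cfg.baseline else 0.0
    for idx in range(n):
        bucket = dict(signal[idx])
        if cfg.noise_sd > 0:
            for mz in sorted(bucket):
                bucket[mz] *= rng.lognormal(0.0, cfg.noise_sd)
        if cfg.bleed_intensity > 0 or per_ion_baseline > 0:
            for mz in BLEED_IONS:
                bucket[mz] = bucket.get(mz, 0.0) + cfg.bleed_intensity + \
                    per_ion_baseline
        spec = StickSpectrum.from_pairs(bucket.items())
        scans.append(Scan(rt=float(rt_axis[idx]), spectrum=spec))

    meta = {
        "pyrolysis_T": cfg.pyrolysis_T,
        "seed": cfg.seed,
        "sample": "+".join(cid for cid, _ in formulation.components),
        "declared": tuple(cid for cid, _ in formulation.components),
    }
    truth = replace(truth, total_area=float(sum(truth.areas.values())))
    return Chromatogram(scans=tuple(scans), metadata=meta), truth


def simulate_temperature_series(formulation: Formulation,
                                library: PyroLibrary, cfg: SimConfig,
                                temps: Sequence[float] = (200, 400, 600, 800,
                                                          1000),
                                ) -> list[tuple[float, Chromatogram]]:
    """Simulate the same formulation across a pyrolysis temperature grid."""
    if not temps:
        raise ValueError("temperature grid must be non-empty")
    if list(temps) != sorted(temps):
        raise ValueError("temperatures must be sorted ascending")
    out = []
    for i, temp in enumerate(temps):
        run_cfg = replace(cfg, pyrolysis_T=float(temp), seed=cfg.seed + i)
        chrom, _ = simulate_pyrogram(formulation, library, run_cfg)
        out.append((float(temp), chrom))
    return out
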