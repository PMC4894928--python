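"""Hazard prediction for identified pigments and polymers.

Once a pigment is identified, its library decomposition products are known
even when a particular run did not show them all -- pyrolysis fragment
patterns approximate what laser removal or strong sunlight can liberate
from tattooed skin.  The report therefore lists every hazard-annotated
fragment of every identified parent: fragments observed in the run carry
their measured relative peak area, predicted-but-unobserved fragments carry
``None`` (distinguishing "not formed" from "not detected").  Aggregates
are computed over observed rows only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .library import GHS_SEVERITY, PyroLibrary
from .identify import IdentificationResult, assign_fragment_hits
from .peaks import ChromPeak

__all__ = [
    "HazardRow",
    "HazardReport",
    "predict_hazards",
    "predict_hazards_for",
    "carcinogen_area_fraction",
    "render_hazard_table",
]


@dataclass(frozen=True)
class HazardRow:
    compound: str
    parent: str
    ghs_class: str
    ghs_category: str
    rel_area: float | None  # None = predicted but not observed in this run


@dataclass(frozen=True)
class HazardReport:
    sample_id: str
    rows: tuple[HazardRow, ...]
    carcinogen_area_fraction: float
    flags: frozenset[str]  # "cyanide-releasing", "pAA-releasing"

    def __post_init__(self) -> None:
        if not (0 <= self.carcinogen_area_fraction <= 1):
            raise ValueError("carcinogen_area_fraction must be in [0, 1]")


def _sort_key(row: HazardRow) -> tuple:
    return (GHS_SEVERITY.get(row.ghs_category, 99), row.ghs_class,
            row.compound, row.parent)


def predict_hazards_for(identified: Iterable[str], library: PyroLibrary,
                        observed_areas: Mapping[str, float] | None = None,
                        sample_id: str = "sample") -> HazardReport:
    """Hazard report for a set of identified pigment/polymer ids.

    ``observed_areas`` maps fragment names to relative peak areas actually
    measured in the run; fragments absent from it are reported as
    predicted (area ``None``).
    """
    observed = dict(observed_areas or {})
    parents = sorted(set(identified))
    rows: list[HazardRow] = []
    flags: set[str] = set()
    carcinogen_fragments: set[str] = set()
    for pid in parents:
        for fname, _yield in sorted(library.fragments_of(pid).items()):
            rec = library.fragments[fname]
            if "cyanide" in rec.tags:
                flags.add("cyanide-releasing")
            if "pAA" in rec.tags:
                flags.add("pAA-releasing")
            if rec.is_carcinogenic and fname in observed:
                carcinogen_fragments.add(fname)
            for hz in rec.hazards:
                rows.append(HazardRow(
                    compound=fname, parent=pid,
                    ghs_class=hz.ghs_class, ghs_category=hz.ghs_category,
                    rel_area=observed.get(fname)))
    frac = sum(observed[f] for f in carcinogen_fragments)
    return HazardReport(sample_id=sample_id,
                        rows=tuple(sorted(rows, key=_sort_key)),
                        carcinogen_area_fraction=min(1.0, frac),
                        flags=frozenset(flags))


def predict_hazards(result: IdentificationResult, library: PyroLibrary
                    ) -> HazardReport:
    """Hazard report for a fragment-comparison identification result."""
    identified: set[str] = set()
    for grp in result.fragment_groups:
        identified |= grp
    observed: dict[str, float] = {}
    for hit in result.fragment_hits:
        observed[hit.fragment] = observed.get(hit.fragment, 0.0) + \
            hit.peak.rel_area
    return predict_hazards_for(identified, library, observed,
                               sample_id=result.sample_id)


def carcinogen_area_fraction(peaks: Sequence[ChromPeak],
                             library: PyroLibrary,
                             self_min: float = 80.0) -> float:
    """Summed relative area of peaks matched to carcinogenic fragments.

    Each peak is assigned its single best-matching library fragment (same
    winner-takes-peak rule and acceptance threshold as identification);
    the relative areas of peaks whose fragment carries a Carcinogenicity
    annotation are summed.  Additive over disjoint peak sets.
    """
    hits = assign_fragment_hits(peaks, library, self_min=self_min)
    return float(sum(h.peak.rel_area for h in hits
                     if library.fragments[h.fragment].is_carcinogenic))


def render_hazard_table(report: HazardReport) -> str:
    """Plain-text rendering of a hazard report."""
    lines = [f"Hazard report: {report.sample_id}"]
    if report.flags:
        lines.append("Flags: " + ", ".join(sorted(report.flags)))
    lines.append(f"Carcinogen area fraction (observed): "
                 f"{report.carcinogen_area_fraction:.3f}")
    header = f"{'compound':42s} {'parent':12s} {'GHS class':48s} " \
             f"{'cat.':5s} {'rel. area':>9s}"
    lines.append(header)
    lines.append("-" * len(header))
    for row in report.rows:
        area = "  (pred.)" if row.rel_area is None else f"{row.rel_area:9.4f}"
        lines.append(f"{row.compound:42s} {row.parent:12s} "
                     f"{row.ghs_class:48s} {row.ghs_category:5s} {area}")
    return "\n".join(lines)
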