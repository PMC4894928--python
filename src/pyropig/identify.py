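"""The two pyrogram identification procedures and declaration comparison.

Fragment comparison
    Detect TIC peaks, keep those carrying at least 0.2 % of the total
    chromatogram area, and match each retained peak's spectrum against the
    fragment library.  A peak supports only its single best-scoring
    fragment (winner-takes-peak: one co-elution blob must not confirm many
    pigments).  Matches scoring >= 80 against the in-house library are
    accepted; below that an optional fallback library (e.g. a general EI
    collection) is consulted and only matches scoring strictly above 90
    are accepted.  A pigment is reported iff at least ``require_k`` of its
    diagnostic fragments were hit; ambiguity-group members supported by
    exactly the same fragments are reported jointly ("X (or Y)").

Average-mass-spectrum (AMS) screening
    The whole run is collapsed into one average spectrum (30-400 Da,
    bleed ions excluded) and matched against a per-pigment AMS library;
    the single highest match is the hit.  Fast, but structurally blind to
    minor mixture components -- it reports exactly one pigment.

Declaration comparison mirrors the reference-study bookkeeping: each
declared pigment is confirmed (identified directly or via its ambiguity
group) or missing; identified pigments not on the label are
different-from-declaration.  A sample with *unknown* declaration
(``declared=None``) is different from one declared pigment-free
(``declared=set()``): finds on an unlabelled sample are counted as present
but cannot contradict a label that does not exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .library import PyroLibrary
from .peaks import ChromPeak, detect_peaks, filter_by_relative_area
from .spectra import (
    Chromatogram,
    MassWindow,
    NoOverlapDomainError,
    PyropigError,
    StickSpectrum,
    average_mass_spectrum,
    default_ams_window,
    match_score,
)

__all__ = [
    "NoResultsError",
    "FragmentHit",
    "IdentificationResult",
    "identify_by_fragments",
    "identify_by_ams",
    "compare_to_declaration",
    "summarize",
    "Summary",
    "paper_style_percent",
]

CONFIRMED = "confirmed"
MISSING = "missing"
DIFFERENT = "different-from-declaration"
FOUND = "found"  # identified on a sample whose declaration is unknown


class NoResultsError(PyropigError):
    code = "no-results"


@dataclass(frozen=True)
class FragmentHit:
    """One peak assigned to one library fragment."""

    peak: ChromPeak
    fragment: str
    score: float
    source: str  # "self-library" | "fallback-library"

    def __post_init__(self) -> None:
        if self.source == "self-library":
            if self.score < 80:
                raise ValueError("self-library hits require score >= 80")
        elif self.source == "fallback-library":
            if self.score <= 90:
                raise ValueError("fallback-library hits require score > 90")
        else:
            raise ValueError(f"unknown hit source {self.source!r}")


@dataclass(frozen=True)
class IdentificationResult:
    """Per-sample outcome of both evaluation approaches."""

    sample_id: str
    declared: frozenset[str] | None = None
    ams_best: tuple[str, float] | None = None
    #: ambiguity group of the AMS best hit (just {pid} if ungrouped)
    ams_group: frozenset[str] | None = None
    ams_ranking: tuple[tuple[str, float], ...] = ()
    #: each entry is an ambiguity-resolved hit: a frozenset of pids
    fragment_groups: tuple[frozenset[str], ...] = ()
    #: group -> names of the diagnostic fragments that supported it
    fragment_support: Mapping[frozenset[str], frozenset[str]] = \
        field(default_factory=dict)
    fragment_hits: tuple[FragmentHit, ...] = ()
    statuses: Mapping[str, str] = field(default_factory=dict)

    @property
    def identified_pigments(self) -> frozenset[str]:
        out: set[str] = set()
        for grp in self.fragment_groups:
            out |= grp
        return frozenset(out)

    def group_labels(self) -> list[str]:
        return [PyroLibrary.group_label(g) for g in self.fragment_groups]


# ---------------------------------------------------------------------------
# Fragment comparison
# ---------------------------------------------------------------------------

def _best_match(spectrum: StickSpectrum, records: Mapping[str, StickSpectrum],
                window: MassWindow) -> tuple[str | None, float]:
    best_name, best_score = None, -1.0
    for name in sorted(records):
        try:
            score = match_score(spectrum, records[name], window)
        except NoOverlapDomainError:
            continue
        if score > best_score:
            best_name, best_score = name, score
    return best_name, best_score


def assign_fragment_hits(peaks: Sequence[ChromPeak], library: PyroLibrary,
                         self_min: float = 80.0, fallback_min: float = 90.0,
                         fallback_library: Mapping[str, StickSpectrum] | None
                         = None,
                         window: MassWindow | None = None,
                         log=None) -> list[FragmentHit]:
    """Winner-takes-peak fragment assignment with the two-tier threshold."""
    window = window or MassWindow.open()
    refs = {name: rec.spectrum for name, rec in library.fragments.items()}
    hits: list[FragmentHit] = []
    for peak in peaks:
        name, score = _best_match(peak.spectrum, refs, window)
        if name is not None and score >= self_min:
            hits.append(FragmentHit(peak, name, score, "self-library"))
            if log:
                log.debug("peak rt=%.1f: %s (score %.1f, self-library)",
                          peak.rt_apex, name, score)
            continue
        if fallback_library:
            fb_name, fb_score = _best_match(peak.spectrum, fallback_library,
                                            window)
            if fb_name is not None and fb_score > fallback_min:
                hits.append(FragmentHit(peak, fb_name, fb_score,
                                        "fallback-library"))
                if log:
                    log.debug("peak rt=%.1f: %s (score %.1f, fallback)",
                              peak.rt_apex, fb_name, fb_score)
                continue
        if log:
            log.debug("peak rt=%.1f: unassigned (best %s at %.1f)",
                      peak.rt_apex, name, score)
    return hits


def _resolve_groups(library: PyroLibrary, hit_fragments: frozenset[str]
                    ) -> tuple[tuple[frozenset[str], ...],
                               dict[frozenset[str], frozenset[str]]]:
    """Apply diagnostic rules and merge ambiguity-group members.

    Members of an ambiguity group whose matched diagnostic fragments are
    identical are reported jointly; unidentifiable entries never appear.
    """
    satisfied: dict[str, frozenset[str]] = {}
    for pid in library.identifiable_pigments:
        entry = library.pigments[pid]
        matched = frozenset(entry.diagnostic_fragments) & hit_fragments
        if len(matched) >= entry.require_k:
            satisfied[pid] = matched
    merged: dict[tuple, set[str]] = {}
    for pid, matched in satisfied.items():
        entry = library.pigments[pid]
        key = (entry.ambiguity_group or f"solo::{pid}", matched)
        merged.setdefault(key, set()).add(pid)
    groups = tuple(sorted((frozenset(m) for m in merged.values()),
                          key=lambda g: sorted(g)))
    support = {frozenset(m): key[1] for key, m in merged.items()}
    return groups, support


def identify_by_fragments(chrom: Chromatogram, library: PyroLibrary,
                          min_frac: float = 0.002,
                          self_min: float = 80.0,
                          fallback_min: float = 90.0,
                          fallback_library: Mapping[str, StickSpectrum] | None
                          = None,
                          spectrum_mode: str = "averaged",
                          sample_id: str | None = None,
                          log=None) -> IdentificationResult:
    """Peak-wise fragment comparison (the thorough evaluation approach)."""
    peaks = detect_peaks(chrom, spectrum_mode=spectrum_mode)
    kept = filter_by_relative_area(peaks, min_frac)
    if log:
        for p in peaks:
            log.debug("peak rt=%.1f rel_area=%.4f %s", p.rt_apex, p.rel_area,
                      "kept" if p.rel_area >= min_frac else "dropped")
    hits = assign_fragment_hits(kept, library, self_min, fallback_min,
                                fallback_library, log=log)
    hit_fragments = frozenset(h.fragment for h in hits)
    groups, support = _resolve_groups(library, hit_fragments)
    sid = sample_id or str(chrom.metadata.get("sample", "sample"))
    return IdentificationResult(
        sample_id=sid,
        ams_best=None,
        fragment_groups=groups,
        fragment_support=support,
        fragment_hits=tuple(hits),
    )


# ---------------------------------------------------------------------------
# AMS screening
# ---------------------------------------------------------------------------

def identify_by_ams(chrom: Chromatogram,
                    ams_library: Mapping[str, StickSpectrum],
                    window: MassWindow | None = None,
                    library: PyroLibrary | None = None
                    ) -> tuple[tuple[str, float],
                               tuple[tuple[str, float], ...]]:
    """Single-best-hit AMS screening.

    Returns ``(best, ranking)`` where ``ranking`` is sorted by score
    descending with ties broken by lexicographic pigment id, and ``best``
    is rank 1.  Exactly one hit is reported -- the method's deliberate
    structural limitation on mixtures.
    """
    if not ams_library:
        raise NoResultsError("AMS library is empty")
    window = window or default_ams_window()
    sample_ams = average_mass_spectrum(chrom, window)
    scored = []
    for pid in sorted(ams_library):
        try:
            score = match_score(sample_ams, ams_library[pid], window)
        except NoOverlapDomainError:
            score = 0.0
        scored.append((pid, score))
    ranking = tuple(sorted(scored, key=lambda t: (-t[1], t[0])))
    return ranking[0], ranking


def identify(chrom: Chromatogram, library: PyroLibrary,
             ams_library: Mapping[str, StickSpectrum] | None = None,
             declared: Iterable[str] | None = None,
             window: MassWindow | None = None,
             **fragment_kwargs) -> IdentificationResult:
    """Run both evaluation approaches and compare to the declaration."""
    result = identify_by_fragments(chrom, library, **fragment_kwargs)
    if ams_library:
        best, ranking = identify_by_ams(chrom, ams_library, window, library)
        group = (library.group_members(best[0]) if best[0] in library.pigments
                 else frozenset({best[0]}))
        result = replace(result, ams_best=best, ams_group=group,
                         ams_ranking=ranking)
    decl = frozenset(declared) if declared is not None else None
    statuses = compare_to_declaration(result, decl)
    return replace(result, declared=decl, statuses=statuses)


# ---------------------------------------------------------------------------
# Declaration comparison & summary
# ---------------------------------------------------------------------------

def compare_to_declaration(result: IdentificationResult,
                           declared: frozenset[str] | None
                           ) -> dict[str, str]:
    """Status per pigment: confirmed / missing / different-from-declaration.

    Group hits count as confirming any declared member.  With an unknown
    declaration (``None``) identified groups get status ``found``: present,
    but unable to contradict a nonexistent label.
    """
    statuses: dict[str, str] = {}
    if declared is None:
        for grp in result.fragment_groups:
            statuses[PyroLibrary.group_label(grp)] = FOUND
        return statuses
    for pid in sorted(declared):
        confirmed = any(pid in grp for grp in result.fragment_groups)
        statuses[pid] = CONFIRMED if confirmed else MISSING
    for grp in result.fragment_groups:
        if not grp & declared:
            statuses[PyroLibrary.group_label(grp)] = DIFFERENT
    return statuses


def _ams_is_wrong_or_absent(result: IdentificationResult) -> bool:
    if result.ams_best is None:
        return True
    if result.declared is None:
        return False
    group = result.ams_group or frozenset({result.ams_best[0]})
    return not (group & result.declared)


@dataclass(frozen=True)
class Summary:
    """Declaration-comparison summary over a batch of samples.

    Percentages carry two significant figures, the precision of the
    reference study's summary rows; exact fractions are kept alongside.
    """

    n_samples: int
    n_pigments: int
    ams_wrong: int
    frag_wrong: int
    frag_missing: int

    @property
    def ams_wrong_fraction(self) -> float:
        return self.ams_wrong / self.n_samples

    @property
    def ams_hit_rate(self) -> float:
        return 1.0 - self.ams_wrong_fraction

    @property
    def frag_wrong_fraction(self) -> float:
        return self.frag_wrong / self.n_pigments if self.n_pigments else 0.0

    @property
    def frag_missing_fraction(self) -> float:
        return self.frag_missing / self.n_pigments if self.n_pigments else 0.0

    @property
    def frag_identified_fraction(self) -> float:
        return 1.0 - self.frag_missing_fraction

    def percents(self) -> dict[str, str]:
        return {
            "ams_wrong": paper_style_percent(self.ams_wrong_fraction),
            "frag_wrong": paper_style_percent(self.frag_wrong_fraction),
            "frag_missing": paper_style_percent(self.frag_missing_fraction),
        }

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_pigments": self.n_pigments,
            "ams_wrong": self.ams_wrong,
            "frag_wrong": self.frag_wrong,
            "frag_missing": self.frag_missing,
            "ams_wrong_pct": round(100 * self.ams_wrong_fraction, 1),
            "frag_wrong_pct": round(100 * self.frag_wrong_fraction, 1),
            "frag_missing_pct": round(100 * self.frag_missing_fraction, 1),
            "percent_style": self.percents(),
        }


def paper_style_percent(fraction: float) -> str:
    """Two-significant-figure percentage, e.g. 0.0714 -> ``"7.1 %"``."""
    pct = 100 * fraction
    if pct == 0:
        return "0 %"
    return f"{float(f'{pct:.2g}'):g} %"


def summarize(results: Sequence[IdentificationResult]) -> Summary:
    """Batch summary statistics.

    AMS side: fraction of samples whose single best hit is wrong or
    absent.  Fragment side: wrong identifications and missing pigments
    over the total number of pigments present (a sample with unknown
    declaration contributes its finds to the denominator; wrong finds on
    labelled samples are numerator-only, matching the reference
    bookkeeping).
    """
    if not results:
        raise NoResultsError("summarize needs at least one result")
    n_pigments = 0
    ams_wrong = frag_wrong = frag_missing = 0
    for res in results:
        statuses = res.statuses or compare_to_declaration(res, res.declared)
        if _ams_is_wrong_or_absent(res):
            ams_wrong += 1
        if res.declared is None:
            n_pigments += len(res.fragment_groups)
        else:
            n_pigments += len(res.declared)
        frag_wrong += sum(1 for s in statuses.values() if s == DIFFERENT)
        frag_missing += sum(1 for s in statuses.values() if s == MISSING)
    return Summary(n_samples=len(results), n_pigments=n_pigments,
                   ams_wrong=ams_wrong, frag_wrong=frag_wrong,
                   frag_missing=frag_missing)
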