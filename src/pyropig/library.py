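"""The pyrogram knowledge base.

A library bundles three kinds of records:

* :class:`FragmentRecord` -- a pyrolysis product with its unit-mass EI
  reference spectrum, optional molecular formula (validated against the
  stored nominal mass), GHS hazard annotations, and the pigments/polymers
  that produce it together with a relative yield per parent.
* :class:`PigmentEntry` -- a pigment or polymer with its chemical class,
  diagnostic-fragment rule (a set of fragment names of which ``require_k``
  must be observed, k in {1, 2, 3}), optional ambiguity group (pigments
  with indistinguishable pyrolysis patterns are reported jointly), an
  ``identifiable`` flag (quinacridones and some compact polycyclics lack
  specific cleavage sites and ship with no rule), and a German-regulation
  "prohibited" flag with a separate ``disputed`` marker for the contested
  hair-dye-clause cases.
* AMS reference spectra (optional in the file; usually built at run time
  from reference runs with :func:`build_ams_library`).

The library file is a single structured, diffable UTF-8 text document with
``[fragment]``, ``[pigment]`` and ``[ams]`` sections; spectra are embedded
as MSP blocks (``Name:``/``Formula:``/``Num Peaks:`` plus ``mz intensity;``
lines).  Loading is total: it either yields a fully cross-referenced,
validated library or fails naming the offending record -- no partial loads.

Unknown pyrolysis products ("unknown-426", "unknown-211") are first-class
records without a formula: they are unique to certain pigments and carry
diagnostic weight.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from .spectra import (
    Chromatogram,
    EmptySpectrumError,
    MassWindow,
    PyropigError,
    StickSpectrum,
    average_mass_spectrum,
    nominal_mass,
    normalize,
    read_msp,
)

__all__ = [
    "LibraryIntegrityError",
    "MassMismatchError",
    "HazardAnnotation",
    "FragmentRecord",
    "PigmentEntry",
    "PyroLibrary",
    "load_library",
    "loads_library",
    "build_ams_library",
    "default_library",
    "default_library_path",
    "CHEM_CLASSES",
    "GHS_CATEGORIES",
]


class LibraryIntegrityError(PyropigError):
    code = "library-integrity"


class MassMismatchError(PyropigError):
    code = "mass-mismatch"


CHEM_CLASSES = frozenset({
    "phthalocyanine", "azo", "diazo", "diketopyrrolopyrrole",
    "quinophthalone", "quinacridone", "triphendioxazine",
    "polycyclic-other", "polymer", "additive",
})

#: Closed set of GHS categories used in annotations.
GHS_CATEGORIES = frozenset({"1", "1A", "1B", "2", "n.a."})

#: Severity order for hazard-report sorting (most severe first).
GHS_SEVERITY = {"1A": 0, "1B": 1, "1": 2, "2": 3, "n.a.": 4}


@dataclass(frozen=True)
class HazardAnnotation:
    """One GHS classification row, e.g. Carcinogenicity / 1B."""

    ghs_class: str
    ghs_category: str
    ld50_oral_rat: float | None = None  # mg/kg, optional

    def __post_init__(self) -> None:
        if self.ghs_category not in GHS_CATEGORIES:
            raise ValueError(
                f"GHS category {self.ghs_category!r} not in "
                f"{sorted(GHS_CATEGORIES)}")

    @property
    def is_carcinogen(self) -> bool:
        return self.ghs_class.lower().startswith("carcinogen")


@dataclass(frozen=True)
class FragmentRecord:
    """A library pyrolysis fragment.

    ``parents`` maps producing pigment/polymer identifiers to the
    fragment's relative yield in that parent's pyrogram (dimensionless,
    relative to the parent's most abundant fragment).  ``tags`` marks
    special roles: ``pAA`` (carcinogenic primary aromatic amine),
    ``cyanide`` (cyanide-releasing), ``impurity`` (temperature profile is
    constant-then-declining rather than a decomposition onset).
    """

    name: str
    nominal_mz: int
    spectrum: StickSpectrum
    formula: str | None = None
    hazards: tuple[HazardAnnotation, ...] = ()
    parents: Mapping[str, float] = field(default_factory=dict)
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.formula is not None:
            calc = nominal_mass(self.formula)
            if calc != self.nominal_mz:
                raise MassMismatchError(
                    f"fragment {self.name!r}: formula {self.formula} gives "
                    f"nominal mass {calc}, record says {self.nominal_mz}")
        object.__setattr__(self, "tags", frozenset(self.tags))

    @property
    def is_carcinogenic(self) -> bool:
        return any(h.is_carcinogen for h in self.hazards)


@dataclass(frozen=True)
class PigmentEntry:
    pid: str
    chem_class: str
    diagnostic_fragments: tuple[str, ...] = ()
    require_k: int = 0
    ambiguity_group: str | None = None
    identifiable: bool = True
    prohibited_de: bool = False
    prohibited_disputed: bool = False

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValueError(f"{self.pid}: unknown chemical class "
                             f"{self.chem_class!r}")
        if not self.identifiable and self.diagnostic_fragments:
            raise ValueError(
                f"{self.pid}: unidentifiable entries must have an empty "
                "diagnostic rule")
        if self.identifiable:
            if self.require_k not in (1, 2, 3):
                raise ValueError(f"{self.pid}: require_k must be 1-3")
            if self.require_k > len(self.diagnostic_fragments):
                raise ValueError(
                    f"{self.pid}: require_k exceeds listed diagnostics")


@dataclass(frozen=True)
class PyroLibrary:
    fragments: dict[str, FragmentRecord]
    pigments: dict[str, PigmentEntry]
    ams: dict[str, StickSpectrum] = field(default_factory=dict)
    checksum: str = ""

    def fragments_of(self, pid: str) -> dict[str, float]:
        """Fragment name -> relative yield for one pigment/polymer."""
        return {name: rec.parents[pid]
                for name, rec in self.fragments.items()
                if pid in rec.parents}

    def group_members(self, pid: str) -> frozenset[str]:
        """The pigment's ambiguity group (itself if ungrouped)."""
        entry = self.pigments[pid]
        if entry.ambiguity_group is None:
            return frozenset({pid})
        return frozenset(p for p, e in self.pigments.items()
                         if e.ambiguity_group == entry.ambiguity_group)

    @staticmethod
    def group_label(members: frozenset[str]) -> str:
        """Paper-style joint label, e.g. ``"P.R.170 (or P.R.210)"``."""
        ordered = sorted(members)
        if len(ordered) == 1:
            return ordered[0]
        return f"{ordered[0]} (or {', '.join(ordered[1:])})"

    @property
    def identifiable_pigments(self) -> list[str]:
        return sorted(p for p, e in self.pigments.items() if e.identifiable)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_hazards(text: str) -> tuple[HazardAnnotation, ...]:
    out = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "|" not in chunk:
            raise LibraryIntegrityError(
                f"hazard entry {chunk!r} must be 'Class|Category'")
        cls, _, cat = chunk.rpartition("|")
        out.append(HazardAnnotation(ghs_class=cls.strip(),
                                    ghs_category=cat.strip()))
    return tuple(out)


def _parse_parents(text: str) -> dict[str, float]:
    parents: dict[str, float] = {}
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        pid, _, y = chunk.rpartition(":")
        if not pid:
            raise LibraryIntegrityError(
                f"parent entry {chunk!r} must be 'pid:yield'")
        parents[pid.strip()] = float(y)
    return parents


_BOOL = {"yes": True, "true": True, "no": False, "false": False}


def _fragment_from_section(body: str) -> FragmentRecord:
    spectra = read_msp(body)
    if len(spectra) != 1:
        raise LibraryIntegrityError("[fragment] section must hold one spectrum")
    spec = spectra[0]
    meta = dict(spec.metadata)
    name = meta.get("name")
    if not name:
        raise LibraryIntegrityError("[fragment] section missing Name")
    if not spec.peaks:
        raise EmptySpectrumError(f"fragment {name!r} has an empty spectrum")
    try:
        return FragmentRecord(
            name=name,
            formula=meta.get("formula") or None,
            nominal_mz=int(meta["nominal_mz"]),
            spectrum=normalize(StickSpectrum(spec.peaks, {"name": name})),
            hazards=_parse_hazards(meta.get("hazards", "")),
            parents=_parse_parents(meta.get("parents", "")),
            tags=frozenset(t.strip() for t in meta.get("tags", "").split(",")
                           if t.strip()),
        )
    except KeyError as exc:
        raise LibraryIntegrityError(
            f"fragment {name!r}: missing field {exc}") from exc


def _pigment_from_section(body: str) -> PigmentEntry:
    meta: dict[str, str] = {}
    for line in body.splitlines():
        line = line.strip()
        if not line:
            continue
        key, _, val = line.partition(":")
        meta[key.strip().lower()] = val.strip()
    pid = meta.get("pid")
    if not pid:
        raise LibraryIntegrityError("[pigment] section missing Pid")
    prohibited = meta.get("prohibited_de", "no").lower()
    diagnostics = tuple(d.strip() for d in meta.get("diagnostic", "").split("|")
                        if d.strip())
    try:
        return PigmentEntry(
            pid=pid,
            chem_class=meta["class"],
            diagnostic_fragments=diagnostics,
            require_k=int(meta.get("require", "0") or 0),
            ambiguity_group=meta.get("ambiguity") or None,
            identifiable=_BOOL[meta.get("identifiable", "yes").lower()],
            prohibited_de=prohibited == "yes",
            prohibited_disputed=prohibited == "disputed",
        )
    except KeyError as exc:
        raise LibraryIntegrityError(
            f"pigment {pid!r}: missing field {exc}") from exc


def loads_library(text: str) -> PyroLibrary:
    """Parse and validate a library document from a string."""
    fragments: dict[str, FragmentRecord] = {}
    pigments: dict[str, PigmentEntry] = {}
    ams: dict[str, StickSpectrum] = {}

    sections: list[tuple[str, list[str]]] = []
    for raw in text.splitlines():
        stripped = raw.strip()
        if stripped.startswith("#"):
            continue
        if stripped in ("[fragment]", "[pigment]", "[ams]"):
            sections.append((stripped[1:-1], []))
        elif sections:
            sections[-1][1].append(raw)
        elif stripped:
            raise LibraryIntegrityError(
                f"content before first section: {stripped!r}")

    for kind, lines in sections:
        body = "\n".join(lines)
        if kind == "fragment":
            rec = _fragment_from_section(body)
            if rec.name in fragments:
                raise LibraryIntegrityError(f"duplicate fragment {rec.name!r}")
            fragments[rec.name] = rec
        elif kind == "pigment":
            ent = _pigment_from_section(body)
            if ent.pid in pigments:
                raise LibraryIntegrityError(f"duplicate pigment {ent.pid!r}")
            pigments[ent.pid] = ent
        else:
            spectra = read_msp(body)
            if len(spectra) != 1:
                raise LibraryIntegrityError("[ams] section must hold one spectrum")
            pid = spectra[0].metadata.get("name")
            if not pid:
                raise LibraryIntegrityError("[ams] section missing Name")
            ams[pid] = normalize(StickSpectrum(spectra[0].peaks, {"name": pid}))

    # Cross-reference validation: total, no partial loads.
    for name, rec in fragments.items():
        for parent in rec.parents:
            if parent not in pigments:
                raise LibraryIntegrityError(
                    f"fragment {name!r} references unknown parent {parent!r}")
    for pid, ent in pigments.items():
        for diag in ent.diagnostic_fragments:
            if diag not in fragments:
                raise LibraryIntegrityError(
                    f"pigment {pid!r} references unknown fragment {diag!r}")
            if pid not in fragments[diag].parents:
                raise LibraryIntegrityError(
                    f"pigment {pid!r} lists diagnostic {diag!r} that does not "
                    f"name it as parent")
    for pid in ams:
        if pid not in pigments:
            raise LibraryIntegrityError(f"[ams] for unknown pigment {pid!r}")

    checksum = hashlib.sha256(text.encode("utf-8")).hexdigest()
    return PyroLibrary(fragments=fragments, pigments=pigments, ams=ams,
                       checksum=checksum)


def load_library(path) -> PyroLibrary:
    """Load and validate a library file (UTF-8)."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise LibraryIntegrityError(f"cannot read library file {path}: {exc}")
    return loads_library(text)


def build_ams_library(reference_runs: Mapping[str, Chromatogram],
                      window: MassWindow | None = None
                      ) -> dict[str, StickSpectrum]:
    """Average mass spectrum per pigment from reference runs.

    Deterministic; propagates ``empty-spectrum`` with the pigment id
    attached if a run carries no signal inside the window.
    """
    out: dict[str, StickSpectrum] = {}
    for pid in sorted(reference_runs):
        try:
            out[pid] = average_mass_spectrum(reference_runs[pid], window)
        except EmptySpectrumError as exc:
            raise EmptySpectrumError(f"{pid}: {exc}") from exc
    return out


_DEFAULT: PyroLibrary | None = None


def default_library_path() -> Path:
    return Path(resources.files("pyropig") / "data" / "pigment_library.txt")


def default_library() -> PyroLibrary:
    """The shipped pigment/polymer library (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_library(default_library_path())
    return _DEFAULT
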