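"""Workflow plumbing: run configuration, batch pipeline, result files.

Ties the modules into ``simulate -> identify -> hazard-report -> summarize``
workflows.  Thresholds live in a :class:`RunConfig` that can be written to
and read from YAML (``init-config`` emits the full default set), so a run's
threshold choices are reproducible; every result file header carries the
library checksum and, where applicable, the simulation seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .hazard import predict_hazards
from .identify import (
    IdentificationResult,
    Summary,
    compare_to_declaration,
    identify,
    summarize,
)
from .library import PyroLibrary, default_library_path, load_library
from .spectra import (
    Chromatogram,
    DEFAULT_BLEED_MZ,
    MassWindow,
    PyropigError,
    read_chromatogram_csv,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "result_to_dict",
    "load_reference_matrix",
    "reference_matrix_path",
]

log = logging.getLogger("pyropig")


@dataclass
class RunConfig:
    library: str = ""
    window_lo: int = 30
    window_hi: int = 400
    excluded_mz: tuple[int, ...] = tuple(sorted(DEFAULT_BLEED_MZ))
    min_frac: float = 0.002
    self_min: float = 80.0
    fallback_min: float = 90.0
    spectrum_mode: str = "averaged"
    out_dir: str = "results"
    verbosity: int = 0

    def __post_init__(self) -> None:
        for name in ("self_min", "fallback_min"):
            if not (0 <= getattr(self, name) <= 100):
                raise ValueError(f"{name} must be within [0, 100]")
        MassWindow(self.window_lo, self.window_hi)  # validates the window

    @property
    def window(self) -> MassWindow:
        return MassWindow(self.window_lo, self.window_hi,
                          frozenset(self.excluded_mz))

    def to_yaml(self) -> str:
        d = asdict(self)
        d["excluded_mz"] = list(self.excluded_mz)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str, **overrides) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "excluded_mz" in data:
            data["excluded_mz"] = tuple(int(m) for m in data["excluded_mz"])
        return cls(**data)


def result_to_dict(result: IdentificationResult, library: PyroLibrary
                   ) -> dict:
    """JSON-ready per-sample block (with library checksum header)."""
    return {
        "sample": result.sample_id,
        "library_checksum": library.checksum,
        "declared": sorted(result.declared) if result.declared is not None
        else None,
        "ams": {
            "best": list(result.ams_best) if result.ams_best else None,
            "ranking": [list(t) for t in result.ams_ranking[:10]],
        },
        "fragment_groups": [sorted(g) for g in result.fragment_groups],
        "fragment_hits": [
            {"rt": h.peak.rt_apex, "fragment": h.fragment,
             "score": round(h.score, 2), "source": h.source,
             "rel_area": round(h.peak.rel_area, 6)}
            for h in result.fragment_hits
        ],
        "statuses": dict(result.statuses),
    }


def run_pipeline(config: RunConfig,
                 inputs: Sequence[tuple[str, Iterable[str] | None]],
                 ams_library=None,
                 write_hazards: bool = True
                 ) -> tuple[list[IdentificationResult], Summary]:
    """Identify a batch of chromatogram CSV files against declarations.

    ``inputs`` holds ``(csv_path, declared-ids-or-None)`` pairs.  Writes a
    per-sample result JSON (and hazard report) plus an aggregate summary
    JSON under ``config.out_dir``; partial outputs are removed on error.
    """
    library = load_library(config.library or default_library_path())
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: list[IdentificationResult] = []
    try:
        for csv_path, declared in inputs:
            chrom = read_chromatogram_csv(csv_path)
            sid = Path(csv_path).stem
            result = identify(
                chrom, library, ams_library=ams_library, declared=declared,
                window=config.window, min_frac=config.min_frac,
                self_min=config.self_min, fallback_min=config.fallback_min,
                spectrum_mode=config.spectrum_mode, sample_id=sid, log=log)
            results.append(result)
            path = out_dir / f"{sid}.result.json"
            path.write_text(json.dumps(result_to_dict(result, library),
                                       indent=2))
            written.append(path)
            if write_hazards:
                report = predict_hazards(result, library)
                hz_path = out_dir / f"{sid}.hazard.json"
                hz_path.write_text(json.dumps({
                    "sample": report.sample_id,
                    "library_checksum": library.checksum,
                    "flags": sorted(report.flags),
                    "carcinogen_area_fraction":
                        round(report.carcinogen_area_fraction, 6),
                    "rows": [
                        {"compound": r.compound, "parent": r.parent,
                         "ghs_class": r.ghs_class,
                         "ghs_category": r.ghs_category,
                         "rel_area": r.rel_area}
                        for r in report.rows],
                }, indent=2))
                written.append(hz_path)
        summary = summarize(results)
        summary_path = out_dir / "summary.json"
        summary_path.write_text(json.dumps(
            {"library_checksum": library.checksum, **summary.to_dict()},
            indent=2))
    except PyropigError:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return results, summary


# ---------------------------------------------------------------------------
# Reference identification matrix replay
# ---------------------------------------------------------------------------

def reference_matrix_path() -> Path:
    return Path(resources.files("pyropig") / "data" / "reference_idents.csv")


def _parse_groups(cell: str) -> tuple[frozenset[str], ...]:
    if cell.strip() in ("-", ""):
        return ()
    return tuple(frozenset(g.split("|")) for g in cell.split(";"))


def load_reference_matrix(path=None, kind: str | None = None
                          ) -> list[IdentificationResult]:
    """Replay the shipped ink/mix identification matrix.

    Each row is turned into an :class:`IdentificationResult` carrying the
    recorded AMS and fragment-comparison outcomes; statuses are recomputed
    with :func:`compare_to_declaration` (AMS scores were not recorded and
    are set to nan).
    """
    import csv
    import math

    path = Path(path) if path else reference_matrix_path()
    results = []
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(
            line for line in fh if not line.startswith("#"))]
    for row in rows:
        if kind and row["kind"] != kind:
            continue
        declared = (None if row["declared"].strip() == "?"
                    else frozenset(row["declared"].split(";")))
        ams_cell = row["ams"].strip()
        if ams_cell == "-":
            ams_best, ams_group = None, None
        else:
            members = frozenset(ams_cell.split("|"))
            ams_best = (sorted(members)[0], math.nan)
            ams_group = members
        result = IdentificationResult(
            sample_id=row["sample"], declared=declared,
            ams_best=ams_best, ams_group=ams_group,
            fragment_groups=_parse_groups(row["fragment"]))
        statuses = compare_to_declaration(result, declared)
        results.append(dataclasses.replace(result, statuses=statuses))
    return results
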