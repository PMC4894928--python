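"""Both identification procedures, declaration comparison, and summaries."""

import math

import pytest

import pyropig as pp
from pyropig.identify import (
    CONFIRMED,
    DIFFERENT,
    FOUND,
    MISSING,
    FragmentHit,
    IdentificationResult,
    compare_to_declaration,
    identify_by_ams,
    identify_by_fragments,
    paper_style_percent,
    summarize,
)


def run(library, cfg, *pids):
    chrom, _ = pp.simulate_pyrogram(
        pp.Formulation.equal_parts(*pids), library, cfg)
    return chrom


class TestFragmentIdentification:
    def test_pure_run_identifies_exactly_that_pigment(self, library,
                                                      clean_cfg):
        res = identify_by_fragments(run(library, clean_cfg, "P.R.254"),
                                    library)
        assert res.fragment_groups == (frozenset({"P.R.254"}),)

    def test_mixture_reports_both_components(self, library):
        res = identify_by_fragments(
            run(library, pp.SimConfig(seed=21), "P.B.15", "P.V.23"), library)
        assert frozenset({"P.B.15"}) in res.fragment_groups
        assert frozenset({"P.V.23"}) in res.fragment_groups

    def test_quinacridone_component_is_never_reported(self, library):
        res = identify_by_fragments(
            run(library, pp.SimConfig(seed=22), "P.R.122", "P.Y.1"), library)
        assert res.identified_pigments == {"P.Y.1"}

    def test_ambiguity_group_reported_jointly(self, library, clean_cfg):
        res = identify_by_fragments(run(library, clean_cfg, "P.R.170"),
                                    library)
        assert res.fragment_groups == (frozenset({"P.R.170", "P.R.210"}),)
        assert res.group_labels() == ["P.R.170 (or P.R.210)"]

    def test_monotone_in_sensitivity(self, library):
        chrom = run(library, pp.SimConfig(seed=23), "P.R.5", "P.Y.83")
        strict = identify_by_fragments(chrom, library, min_frac=0.01)
        loose = identify_by_fragments(chrom, library, min_frac=0.001)
        assert strict.identified_pigments <= loose.identified_pigments

    def test_hit_threshold_invariants(self):
        peak = pp.ChromPeak(rt_apex=1.0, rt_start=0.0, rt_end=2.0, area=1.0,
                            rel_area=0.5,
                            spectrum=pp.StickSpectrum.from_dict({78: 100}))
        with pytest.raises(ValueError):
            FragmentHit(peak, "benzene", 79.0, "self-library")
        with pytest.raises(ValueError):
            FragmentHit(peak, "benzene", 90.0, "fallback-library")

    def test_fallback_library_requires_higher_score(self, library, clean_cfg):
        """A fragment absent from the in-house library is recovered from a
        fallback collection only above the stricter threshold."""
        chrom = run(library, clean_cfg, "P.R.177")
        spectra = {n: r.spectrum for n, r in library.fragments.items()}
        small = pp.loads_library(
            "[fragment]\nName: benzene\nFormula: C6H6\nNominal_mz: 78\n"
            "Parents: dummy:1.0\nNum Peaks: 1\n78 100;\n\n"
            "[pigment]\nPid: dummy\nClass: polymer\nDiagnostic: benzene\n"
            "Require: 1\nIdentifiable: yes\nProhibited_de: no\n")
        res = identify_by_fragments(chrom, small,
                                    fallback_library=spectra)
        sources = {h.fragment: h.source for h in res.fragment_hits}
        assert sources["1-amino-9,10-anthracenedione"] == "fallback-library"


class TestAmsIdentification:
    def test_pure_run_best_hit(self, library, reference_runs, ams_library):
        best, ranking = identify_by_ams(reference_runs["P.Y.138"],
                                        ams_library)
        assert best[0] == "P.Y.138"
        assert ranking[0] == best
        assert [s for _, s in ranking] == \
            sorted((s for _, s in ranking), reverse=True)

    def test_mixture_yields_single_dominant_hit(self, library, ams_library):
        chrom = run(library, pp.SimConfig(seed=24), "P.R.254", "P.Y.3")
        best, _ = identify_by_ams(chrom, ams_library)
        assert best[0] in {"P.R.254", "P.Y.3"}

    def test_singleton_library_always_wins(self, library, reference_runs,
                                           ams_library):
        best, _ = identify_by_ams(reference_runs["P.B.15"],
                                  {"P.V.23": ams_library["P.V.23"]})
        assert best[0] == "P.V.23"

    def test_all_identifiable_pigments_self_identify(self, library,
                                                     reference_runs,
                                                     ams_library):
        for pid in library.identifiable_pigments:
            best, _ = identify_by_ams(reference_runs[pid], ams_library)
            assert best[0] in library.group_members(pid), pid


class TestCompareToDeclaration:
    def test_group_hit_confirms_declared_member(self):
        res = IdentificationResult(
            "s", fragment_groups=(frozenset({"P.R.170", "P.R.210"}),))
        statuses = compare_to_declaration(res, frozenset({"P.R.170"}))
        assert statuses == {"P.R.170": CONFIRMED}

    def test_partial_confirmation_and_missing(self):
        res = IdentificationResult(
            "s", fragment_groups=(frozenset({"P.Y.74", "P.Y.65"}),))
        statuses = compare_to_declaration(
            res, frozenset({"P.O.13", "P.Y.65"}))
        assert statuses["P.Y.65"] == CONFIRMED
        assert statuses["P.O.13"] == MISSING

    def test_undeclared_find_on_empty_declaration_is_wrong(self):
        res = IdentificationResult(
            "s", fragment_groups=(frozenset({"P.B.15"}),))
        statuses = compare_to_declaration(res, frozenset())
        assert statuses == {"P.B.15": DIFFERENT}

    def test_unknown_declaration_yields_neutral_found(self):
        res = IdentificationResult(
            "s", fragment_groups=(frozenset({"P.B.15"}),))
        assert compare_to_declaration(res, None) == {"P.B.15": FOUND}


class TestSummarize:
    def test_all_confirmed_single_sample(self):
        res = IdentificationResult(
            "s", declared=frozenset({"P.B.15"}),
            ams_best=("P.B.15", 95.0), ams_group=frozenset({"P.B.15"}),
            fragment_groups=(frozenset({"P.B.15"}),))
        summary = summarize([res])
        assert (summary.ams_wrong, summary.frag_wrong,
                summary.frag_missing) == (0, 0, 0)
        assert summary.percents() == {
            "ams_wrong": "0 %", "frag_wrong": "0 %", "frag_missing": "0 %"}

    def test_empty_input_is_error(self):
        with pytest.raises(pp.NoResultsError):
            summarize([])

    def test_absent_ams_counts_as_wrong(self):
        res = IdentificationResult("s", declared=frozenset({"P.B.15"}))
        assert summarize([res]).ams_wrong == 1

    @pytest.mark.parametrize("fraction,text", [
        (2 / 28, "7.1 %"), (3 / 40, "7.5 %"), (8 / 40, "20 %"),
        (4 / 18, "22 %"), (0.0, "0 %"), (7 / 37, "19 %"),
    ])
    def test_percent_formatter_two_significant_figures(self, fraction, text):
        assert paper_style_percent(fraction) == text


class TestEndToEnd:
    def test_identify_populates_statuses_and_ams(self, library, ams_library):
        chrom = run(library, pp.SimConfig(seed=25), "P.R.254", "P.Y.3")
        res = pp.identify(chrom, library, ams_library=ams_library,
                          declared={"P.R.254", "P.Y.3"})
        assert res.statuses["P.R.254"] == CONFIRMED
        assert res.statuses["P.Y.3"] == CONFIRMED
        assert res.ams_best is not None
        assert not math.isnan(res.ams_best[1])
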