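"""Stick-spectrum model: normalization, windows, matching, AMS, masses."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pyropig.spectra import (
    Chromatogram,
    EmptySpectrumError,
    FormulaParseError,
    MassWindow,
    NoOverlapDomainError,
    Scan,
    StickSpectrum,
    average_mass_spectrum,
    match_score,
    nominal_mass,
    normalize,
    read_msp,
    restrict,
    write_msp,
)

from conftest import stick_spectra


def S(d, **meta):
    return StickSpectrum.from_dict(d, metadata=meta)


class TestStickSpectrum:
    def test_binning_sums_coinciding_masses(self):
        spec = StickSpectrum.from_pairs([(78.2, 10.0), (77.9, 5.0), (104.0, 1.0)])
        assert spec.to_dict() == {78: 15.0, 104: 1.0}

    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            StickSpectrum(peaks=((0, 1.0),))
        with pytest.raises(ValueError):
            StickSpectrum(peaks=((100, 1.0), (50, 1.0)))
        with pytest.raises(ValueError):
            StickSpectrum(peaks=((50, -1.0),))

    def test_rt_ordering_enforced(self):
        scans = (Scan(1.0, S({78: 1})), Scan(0.5, S({78: 1})))
        with pytest.raises(ValueError):
            Chromatogram(scans=scans)


class TestNormalize:
    def test_scales_base_peak_to_100(self):
        assert normalize(S({78: 50, 104: 25})).to_dict() == {78: 100.0, 104: 50.0}

    def test_identity_on_normalized_singleton(self):
        assert normalize(S({111: 100})).to_dict() == {111: 100.0}

    @pytest.mark.parametrize("spec", [S({}), S({78: 0.0})])
    def test_degenerate_input_rejected(self, spec):
        with pytest.raises(EmptySpectrumError):
            normalize(spec)


class TestRestrict:
    def test_mass_range_rule(self):
        # species at 28 and 426 Da fall outside the 30-400 screening window
        out = restrict(S({28: 10, 78: 100, 426: 40}), MassWindow(30, 400))
        assert out.to_dict() == {78: 100.0}

    def test_exclusion_removes_sole_peak(self):
        out = restrict(S({78: 100}), MassWindow(30, 400, frozenset({78})))
        assert out.to_dict() == {}

    @given(stick_spectra())
    def test_identity_window(self, spec):
        assert restrict(spec, MassWindow.open()).to_dict() == spec.to_dict()

    @given(stick_spectra(), st.integers(1, 300), st.integers(0, 300))
    def test_idempotent(self, spec, lo, span):
        window = MassWindow(lo, lo + span, frozenset({lo + 1}))
        once = restrict(spec, window)
        assert restrict(once, window).to_dict() == once.to_dict()


class TestMatchScore:
    @given(stick_spectra())
    def test_self_match_is_100(self, spec):
        assert match_score(spec, spec) == pytest.approx(100.0, abs=1e-9)

    def test_disjoint_masses_score_zero(self):
        assert match_score(S({78: 100}), S({104: 100})) == 0.0

    def test_unweighted_cosine_hand_computed(self):
        # (100,50).(50,100) / (|.||.|) = 10000/12500 = 0.8
        score = match_score(S({50: 100, 100: 50}), S({50: 50, 100: 100}),
                            p=0, q=1)
        assert score == pytest.approx(80.0, abs=1e-9)

    def test_unweighted_cosine_agrees_with_matchms(self):
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        a = S({50: 100, 100: 50, 120: 30})
        b = S({50: 60, 100: 90, 130: 10})
        mm = CosineGreedy(tolerance=0.2).pair(
            Spectrum(mz=a.mz.astype(float), intensities=a.intensities,
                     metadata={}, metadata_harmonization=False),
            Spectrum(mz=b.mz.astype(float), intensities=b.intensities,
                     metadata={}, metadata_harmonization=False))
        assert match_score(a, b, p=0, q=1) == \
            pytest.approx(100 * float(mm["score"]), abs=1e-6)

    @given(stick_spectra(), stick_spectra())
    def test_symmetry(self, a, b):
        assert match_score(a, b) == pytest.approx(match_score(b, a), abs=1e-9)

    @given(stick_spectra(), stick_spectra(), st.floats(0.01, 50))
    def test_invariant_under_uniform_scaling(self, a, b, factor):
        scaled = StickSpectrum.from_pairs(
            (mz, i * factor) for mz, i in a.peaks)
        assert match_score(scaled, b) == pytest.approx(match_score(a, b),
                                                       abs=1e-6)

    def test_empty_after_restriction_is_an_error_not_zero(self):
        with pytest.raises(NoOverlapDomainError):
            match_score(S({27: 100}), S({78: 100}), MassWindow(30, 400))


class TestAverageMassSpectrum:
    def test_single_scan_is_identity(self):
        spec = S({78: 40, 104: 80})
        chrom = Chromatogram(scans=(Scan(0.0, spec),))
        ams = average_mass_spectrum(chrom, MassWindow(30, 400))
        assert ams.to_dict() == normalize(spec).to_dict()

    def test_two_scan_summation(self):
        chrom = Chromatogram(scans=(Scan(0.0, S({78: 100})),
                                    Scan(1.0, S({78: 50, 104: 150}))))
        ams = average_mass_spectrum(chrom, MassWindow(30, 400))
        assert ams.to_dict() == {78: 100.0, 104: 100.0}

    def test_depends_only_on_scan_multiset(self):
        specs = [S({78: 10}), S({104: 5, 78: 1}), S({50: 3})]
        fwd = Chromatogram(scans=tuple(
            Scan(float(i), s) for i, s in enumerate(specs)))
        rev = Chromatogram(scans=tuple(
            Scan(float(i), s) for i, s in enumerate(reversed(specs))))
        assert average_mass_spectrum(fwd).to_dict() == \
            average_mass_spectrum(rev).to_dict()

    def test_empty_window_is_error(self):
        chrom = Chromatogram(scans=(Scan(0.0, S({27: 100})),))
        with pytest.raises(EmptySpectrumError):
            average_mass_spectrum(chrom, MassWindow(30, 400))


class TestNominalMass:
    @pytest.mark.parametrize("formula,expected", [
        ("C8H8", 104),      # styrene
        ("H2", 2),
        ("C16H30O2", 254),  # dodecyl methacrylate
        ("C6H6", 78),
        ("C6Cl6", 282),
        ("C10H30O5Si5", 370),
    ])
    def test_known_masses(self, formula, expected):
        assert nominal_mass(formula) == expected

    @pytest.mark.parametrize("bad", ["", "c8h8", "C8H0", "Xq2", "8C"])
    def test_parse_errors(self, bad):
        with pytest.raises(FormulaParseError):
            nominal_mass(bad)

    def test_agrees_with_monoisotopic_oracle_for_library(self, library):
        """Independent check: rounded pyteomics monoisotopic masses."""
        from pyteomics import mass as pmass

        for rec in library.fragments.values():
            if rec.formula is None:
                continue
            mono = pmass.calculate_mass(formula=rec.formula)
            assert int(round(mono)) == nominal_mass(rec.formula), rec.name


class TestMspRoundTrip:
    def test_bit_exact_for_integer_data(self):
        spectra = [
            S({78: 100, 104: 50}, name="benzene-like", formula="C6H6"),
            S({27: 100}, name="tiny"),
        ]
        text = write_msp(spectra)
        back = read_msp(text)
        assert len(back) == 2
        for orig, loaded in zip(spectra, back):
            assert loaded.to_dict() == orig.to_dict()
            assert loaded.metadata["name"] == orig.metadata["name"]
        assert write_msp(back) == text  # stable under re-serialization

    def test_matchms_can_read_our_msp(self, tmp_path):
        from matchms.importing import load_from_msp

        spec = S({78: 100, 104: 50}, name="interop check")
        path = tmp_path / "lib.msp"
        path.write_text(write_msp([spec]))
        loaded = list(load_from_msp(str(path)))
        assert len(loaded) == 1
        assert loaded[0].peaks.mz.tolist() == [78.0, 104.0]
        assert loaded[0].peaks.intensities.tolist() == [100.0, 50.0]

    def test_num_peaks_mismatch_rejected(self):
        with pytest.raises(ValueError):
            read_msp("Name: broken\nNum Peaks: 2\n78 100;\n")
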