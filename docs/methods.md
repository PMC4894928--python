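# Methods

## Scope and data model

`pyropig` operates on centroided, unit-mass EI chromatograms: every scan is
a stick spectrum (integer m/z ≥ 1, nonnegative relative intensities), every
chromatogram a strictly rt-ordered scan list. Quadrupole EI data is unit
resolution, so any finer input is binned by rounding m/z to the nearest
integer and summing intensities; profile spectra, isotope-pattern modelling
and retention-index calibration are out of scope. Instrument method
settings (desorption/injection temperature programs, column geometry) are
carried as run metadata only and never computed on.

Two conventions run through everything:

* **Base-peak normalization** — a normalized spectrum has its largest
  intensity at 100.
* **Rectangle-rule integration on scan index** — the total chromatogram
  area is the sum of per-scan TIC; peak areas are TIC sums over the
  integration range. Scans are evenly spaced in all supported inputs and
  nothing downstream needs sub-scan accuracy, so trapezoid integration on
  rt would only complicate the bookkeeping.

## Spectrum matching

Library searching uses a weighted cosine ("dot product") score scaled to
0–100. Both spectra are restricted to the search window, normalized,
aligned on the union of their m/z bins, weighted by
`w(mz, I) = mz^p * I^q` with defaults `p = 1.3`, `q = 0.53` (the weighting
commonly used for EI identity searches: mass-proportional weighting rewards
the structurally informative high-m/z ions, the intensity exponent < 1
compresses dynamic range), and compared by cosine similarity. Commercial
search engines keep their exact formulas proprietary; the weighted cosine
is a reproducible, monotone surrogate that preserves the scale semantics
the thresholds rely on (100 = identical, 0 = disjoint). Both exponents are
arguments, so unweighted cosine (`p=0, q=1`) is available and is
cross-checked against an independent implementation in the tests.

A spectrum that is *empty after window restriction* raises a distinct
`no-overlap-domain` error rather than scoring 0: "these two spectra share
no search domain" and "these spectra disagree" must not be conflated
(hydrogen cyanide at m/z 27 simply does not exist inside a 30–400 Da
window).

**Thresholds.** Fragment hits require a score of at least 80 against the
in-house library ("below 80" triggers the fallback, so 80 itself is
accepted); hits from the fallback collection must score strictly above 90.
Both are configurable.

**Window.** The screening window defaults to 30–400 Da with the canonical
siloxane column-bleed ions {73, 147, 207, 281, 355} excluded. The bleed
list is configurable; these five are the classic polysiloxane background
series.

## Peak processing

TIC peaks are detected as local maxima with prominence above a fraction
(default 0.01) of the maximum TIC (`scipy.signal.find_peaks`), with
integration bounds at the nearest flanking local minima; a valley scan
shared by adjacent peaks contributes half its TIC to each, so relative
areas can never sum past 1. Relative area is measured against the *total
chromatogram area* (all scans), not the sum of detected peak areas, and
the identification layer keeps peaks carrying at least 0.2 % of the total
(inclusive).

Peak spectra are scan-averaged over the integration range (an apex-only
mode is available; background-subtracted apex picking and peak averaging
are both defensible and vendor software does not say which it uses — peak
averaging is the default because it is the less noisy statistic). Before
averaging, the per-m/z *median over all scans* is subtracted: ions present
in most scans at a constant level (column bleed, a constant baseline
offset) are removed exactly, while genuine peak ions, present in only a
few scans, have median 0 and pass through untouched. This correction
matters more here than its size suggests: under mass-proportional
weighting, a bleed ion at m/z 355 contaminating a peak spectrum at 1 % of
the base peak carries roughly two-thirds of the base peak's weight and can
drag a correct match below threshold. Integrated areas are always computed
on the raw TIC. Co-eluting components are deliberately *not* deconvolved:
overlapping peaks merge into one mixed spectrum, reproducing a real
failure mode the identification layer must tolerate.

## The library

The library is one human-editable UTF-8 text file with `[fragment]`,
`[pigment]` and optional `[ams]` sections; spectra are embedded MSP blocks
(`Name:`, `Formula:`, `Num Peaks:`, `mz intensity;`). Loading is total:
either every cross-reference resolves and every formula-bearing record
passes the nominal-mass gate (`nominal_mass(formula) == nominal_mz`,
computed from a built-in integer table of most-abundant-isotope masses),
or loading fails naming the offending record. Unknown pyrolysis products
are first-class records (`unknown-426`, `unknown-211`) with a nominal mass
and spectrum but no formula — they are unique to particular pigments and
carry full diagnostic weight. Note the mass convention: a record's
`nominal_mz` is the *molecular* nominal mass (toluene: 92), while its
spectrum's base peak may be a fragment ion (toluene: 91).

Each pigment entry carries a chemical class, a diagnostic rule (a fragment
set of which `require_k` ∈ {1, 2, 3} must be observed; default
`min(2, listed)`), an optional ambiguity group, an `identifiable` flag and
a German-regulation `prohibited` flag with a separate `disputed` marker for
the contested hair-dye-clause cases — a boolean guess would misstate an
actively disputed legal question. Quinacridones (P.R.122, P.V.19,
P.R.202) and the compact polycyclics P.O.43 and P.R.179 lack specific
cleavage sites, yield only low-abundance or generic products, and ship as
`identifiable = false` with empty rules: the method cannot identify them,
and the package encodes that honestly rather than inventing diagnostics.

**Provenance and a synthetic extension.** The shipped fixture covers every
pigment, polymer and fragment association attested in the main text of the
underlying pyrolysis study (phthalocyanine nitriles and cyanide species,
the quinophthalone chlorobenzenes/TIF/426-Da unknown, the
triphendioxazine carbazoles, the diketopyrrolopyrrole benzonitriles, the
polymer products with their GHS rows, the diazo pAAs). The per-pigment
fragment tables of that study's supplement were not available, so for azo
pigments that appear only in its sample matrices the diagnostic fragments
are *chemically plausible* azo/amide cleavage products (coupling-component
amines, pAAs, naphthols) — synthetic library content, marked as such in
the file header. They were chosen under one structural constraint,
enforced by a test: every identifiable pigment keeps at least one
diagnostic fragment unique to its ambiguity group, so no two-component
mixture of other pigments can fake its rule. Reference EI spectra are
likewise synthetic sticks (molecular ion plus a few plausible losses), not
measured spectra.

## Identification

**Fragment comparison.** Detect peaks → keep ≥ 0.2 % → match each kept
peak against all fragment records over the full mass range (the window
restriction belongs to AMS screening; a fragment eluting below 30 Da is
still a valid peak match). A peak supports only its single best-scoring
fragment (*winner-takes-peak*): without this rule one co-elution blob
could confirm several pigments at once. A pigment is reported iff its
rule's `require_k` is met; ambiguity-group members supported by identical
fragment sets are merged and reported jointly ("P.R.170 (or P.R.210)").
Unidentifiable entries never appear by construction.

**AMS screening.** The whole run is summed into one average mass spectrum
(per-scan summation; an optional rt range can exclude a solvent-drying
phase), restricted to 30–400 Da minus bleed ions, and matched against a
per-pigment AMS library; ranking is by score descending with ties broken
by lexicographic pigment id, and *exactly one* hit — the top of the
ranking — is reported. The single-best-match semantics is the method's
deliberate structural limitation: on a two-pigment mixture it names the
dominant component and misses the other, which the tests demonstrate while
the fragment approach recovers both.

**Declaration comparison.** Each declared pigment is `confirmed`
(identified directly or via its ambiguity group) or `missing`; identified
pigments not on the label are `different-from-declaration`. A sample with
*unknown* declaration (`None`) is distinct from one declared pigment-free
(`set()`): finds on an unlabelled sample count as present (`found`) but
cannot contradict a label that does not exist. Batch summaries report, on
the AMS side, the fraction of samples whose best hit is wrong or absent
(a correct-but-partial hit on a mixture counts as correct — the reference
bookkeeping implies exactly this), and on the fragment side wrong and
missing counts over the total pigments present (declared pigments, plus
finds on unlabelled samples; wrong finds on labelled samples are
numerator-only). Unidentifiable pigments count as missing when declared.
Percentages are printed at two significant figures, the precision of the
reference study's summary rows; exact fractions are always available.

**A reference-matrix caveat.** The shipped reference matrix (28 inks, 18
mixtures) replayed through `summarize` reproduces five of the six published
summary statistics exactly (7.1 % / 7.5 % / 20 % on inks, 22 % / 0 % on
mixtures). The sixth — missing pigments in mixtures — is published as
"6/37 = 16.7 %", which is internally inconsistent twice over: 6/37 is
16.2 %, and recomputing statuses from the published per-sample outcomes
counts 7 missing (the mixture-13 quinacridone is declared, absent from the
fragment column, and the accompanying narrative states all quinacridones
were missed, yet it is absent from the published count). `pyropig` reports
the recomputed 7/37 = 18.9 % and the corresponding acceptance check is
knowingly left failing rather than special-cased.

## Hazard prediction

For every identified pigment/polymer the report lists all hazard-annotated
library fragments, one row per GHS classification (a compound can carry
several, e.g. styrene: skin irritation Cat. 2 and STOT RE Cat. 1), sorted
most-severe-first (1A < 1B < 1 < 2 < n.a.). Fragments observed in the run
carry their measured relative area; predicted-but-unobserved fragments
carry `None`, not 0 — the tool's purpose includes predicting what laser or
sunlight exposure could liberate, so "not formed" and "not detected" must
stay distinguishable. Flags mark cyanide-releasing parents
(phthalocyanines) and pAA-releasing parents (azo/diazo pigments). The
carcinogen area fraction sums the relative areas of peaks whose best
fragment match carries a Carcinogenicity annotation; aggregates use
observed rows only. LD50 annotation fields exist but are empty in the
shipped fixture. Dose/exposure modelling and legal adjudication beyond the
prohibited flag are non-goals.

## The synthetic generator

The generator exists to give every analysis stage inputs with the
statistical structure it assumes. Each library fragment of each
formulation component contributes a Gaussian TIC peak (σ = 2 scans,
truncated at 4σ) at a fragment-specific reference retention time; the
scans under it carry the fragment's reference spectrum scaled to the
envelope. Reference rts are synthetic library metadata, spread evenly over
the run in order of nominal mass (a volatility proxy): identification is
spectrum-driven, so rts only shape co-elution stress tests. Peak height is
`weight × fragment yield × temperature factor × intensity_scale`.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| `n_scans` | 600 | enough to resolve all ~70 library fragments at σ = 2 |
| `rt_start..rt_end` | 60–1860 s | a 30-min run after a solvent-vent delay |
| `peak_width` | 2 scans (σ) | sharp capillary-GC peaks at 3-s scan intervals |
| `noise_sd` | 0.05 | multiplicative lognormal on every stick; ~5 % intensity scatter, the regime where matching is easy but thresholds are exercised |
| `bleed_intensity` | 0.1/ion/scan | constant background a few percent of typical analyte signal — a conditioned column; large enough to exercise the exclusion list and background subtraction, small enough not to distort relative areas |
| `coelution_jitter` | 0.5 scans | run-to-run rt wobble |
| `pyrolysis_T` | 800 °C | the temperature at which all covered classes decompose |

Fragment yield versus temperature follows a logistic onset per chemical
class — azo/diazo midpoint 300 °C (cleavage begins near 200 °C),
diketopyrrolopyrrole/triphendioxazine 500 °C, quinophthalone 550 °C,
polycyclics 600 °C, phthalocyanines and quinacridones 750 °C (essentially
unaffected below ~600–800 °C) — while fragments tagged `impurity` (TIF,
xylene, the 426-Da unknown) stay constant to 600 °C and decay
exponentially above: impurities are consumed, not formed, at high
temperature. The curves target qualitative onsets only; absolute
per-temperature yields were never published as numbers and are not
modelled. The diazo pigment P.O.34 is programmed with relative yields
0.25 (3,3′-dichlorobenzidine) versus 1.0 (its pyrazolone), making the pAA
exactly 20 % of the programmed area — the reported upper range for azo
pigments — which the detector recovers within ±0.02.

Ground truth records exact pre-noise areas per (component, fragment), so
closure tests can demand near-exact recovery on noise-free input.

**What passing tests do and do not show.** Generator peaks are clean
Gaussians built *from the same reference spectra the library matches
against*; real EI spectra differ from the synthetic sticks, real peaks
tail, baselines drift, and matrix compounds add peaks the library has
never seen. Green round-trip and mixture tests therefore establish the
*internal soundness* of the pipeline — thresholds, rules, bookkeeping,
the structural AMS limitation — not field performance on instrument data.
The replayed reference matrix is the only link to real measurements, and
it validates the summary arithmetic, not the spectral matching.

## Numerical choices and degenerate inputs

* Cosine values are clipped to [0, 1] before scaling so self-matches are
  exactly 100 despite float fuzz.
* Ties in AMS ranking break lexicographically by pigment id; fragment
  ranking inside a peak is deterministic (sorted name order, strict
  greater-than to replace the incumbent).
* Empty or all-zero spectra, empty chromatograms, too few scans (< 3),
  unknown formulas/elements, dangling library references and unknown
  formulation components all raise typed errors with stable codes
  (`empty-spectrum`, `no-overlap-domain`, `too-few-scans`,
  `empty-chromatogram`, `formula-parse`, `library-integrity`,
  `mass-mismatch`, `unknown-component`, `no-results`); the CLI maps any of
  them to a nonzero exit and removes partial outputs.
* MSP serialization writes integer intensities without a decimal point, so
  integer libraries round-trip bit-exactly; `repr` is used for floats.

## Problem sizes

The shipped checks run on desk-scale problems: 600-scan simulations
(~70 chromatographic peaks over ~300 m/z channels), a 69-fragment /
40-entry library, pure-run round-trips over all 35 identifiable entries, a
20-seed two-component mixture study, 5-point temperature series and a
1000-spectrum self-match sweep — a few tens of seconds end to end. All
randomness is seeded; reruns are bit-identical.
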