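# Methods

`glycotrace` quantifies glycogen content and turnover from measurements of
glucose before and after acid hydrolysis, by direct-infusion ultra-high
resolution FTMS and 1D ¹H NMR, in stable isotope resolved metabolomics
(SIRM) experiments with ¹³C₆- and/or ²H₇-glucose tracers. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## The computation chain

For each sample the pipeline computes

```
net glucose (nmol)      = post-hydrolysis glucose − pre-hydrolysis glucose
glycogen (µg)           = net glucose / 6.17
corrected glycogen (µg) = glycogen / hydrolysis efficiency
content (µg/mg)         = corrected glycogen / mg protein (or residue weight)
```

6.17 µmol glucose per mg glycogen is the residue equivalent: a polymerized
glucose unit weighs glucose (180.06 g/mol) minus water (18.01 g/mol) =
162.05 g/mol, and 1000/162.05 rounds to 6.17. The hydrolysis efficiency is
the recovery measured on a glycogen standard digested alongside the
samples; values slightly above 1 (standard-run variability) are accepted
with a flag, never clipped. Negative net glucose propagates with a flag. A
pre-hydrolysis value below the limit of quantification is treated as zero
when flagged as such.

Enrichment summaries derive from the same quantities: fractional enrichment
100·L/(L+U) for a labeled mass L against unlabeled U; the isotopologue
split unlabeled / fully labeled / scrambled from the species-wise
(post − pre) difference; and the NMR-visible fraction as the intact-extract
NMR glycogen over the hydrolysis-determined total. Reports print masses and
percentages at one decimal (integer percent for the headline enrichment
comparison); all arithmetic is done at full precision.

## Isotopologue model

Glucose (C₆H₁₂O₆) has 6 labelable carbons but only 7 labelable hydrogens:
the 5 hydroxyl protons exchange with aqueous solvent and cannot retain ²H,
which is why the heaviest deuterated species is ²H₇. Enumeration over the
traced elements is the full cartesian product (7 species for ¹³C, 8 for
²H, 56 for both). Exact masses use an embedded IUPAC-2021 isotope table;
¹³C adds 1.0033548 Da, ²H adds 1.0062767 Da, so swapped-label near-isobars
differ by 2.92 mDa — the separation that motivates resolving powers of
500,000–1,000,000.

Resolving power is FWHM-based, quoted at m/z 200, and scaled as
R(m) = R₂₀₀·√(200/m) (FT-analyzer convention; the instrument setting alone
does not fix the scaling law, so this choice is recorded in config). Two
masses count as resolved when they differ by at least one FWHM at their
mean. The closed-form minimum R₂₀₀ for the ¹³C₁/²H₁ pair near m/z 182 is
≈59,500 (m/Δm ≈ 6.2×10⁴).

Natural-abundance fine structure is a multinomial expansion over the
non-tracer C, H (including exchangeable), O and N positions. Lines below a
probability floor (default 1e-6) are dropped and the dropped mass is
reported; renormalization is off by default so correction matrices stay
conservative. Adducts: [M+H]⁺ by default (positive-ion infusion), [M+Na]⁺
and [M−H]⁻ available. Only glucose, UDP-glucose, HMF and levulinic acid
formulas are built in; no general composition decomposition is attempted.

## Synthetic data generator

The generator exists so every downstream stage is testable without any
deposited raw data. What it emulates, and what it does not:

**Labeling.** A scenario is (f_unlabeled, f_direct, f_scrambled, p): direct
incorporation puts intact tracer skeletons on the fully labeled species;
scrambled molecules (pentose-phosphate / gluconeogenic rearrangement)
retain each heavy atom independently with probability p, giving a
Binomial(n, p) ladder. Per-position Bernoulli retention is a deliberate
simplification — positional isotopomers are not modeled for MS, where only
mass is observable.

**Hydrolysis.** Sequential first-order kinetics glycogen → glucose → HMF
with Arrhenius rates k = A·exp(−Ea/RT). The functional form is this
package's choice; the default calibration (rates 0.45 and 0.004 min⁻¹ at
110 °C; activation energies 248 and 200 kJ/mol) was fixed against the
observed behavior of microwave-assisted digestion: >90% recovery at
110 °C/10 min, ≥71% at 105 °C/10 min, a broad 105–115 °C plateau with
recovery unimodal in temperature, and net glucose loss to HMF by 30 min.
The effective activation energies are steep compared with textbook
glycosidic-bond hydrolysis; they describe the narrow optimum of this
particular reactor configuration, not elementary kinetics. Pre-existing
free glucose is carried through hydrolysis unchanged — a simplification;
in reality it would degrade slightly too.

**FTMS spectra.** Gaussian peaks at every fine-structure line, σ from the
resolving-power model, area proportional to amount × line probability
(fixed response factor; quantification is ratio-based so its value never
matters). The m/z axis samples only within ±8 FWHM of lines (12 points per
FWHM), which keeps full-range 100–1000 synthesis cheap; additive Gaussian
noise, default sd 0.5% of the tallest peak. The spiked standard
(¹³C₆-glucose for unlabeled samples, ¹³C₆,²H₇ for labeled ones) must be
resolvable from every analyte at the configured resolving power or
synthesis refuses. No chromatography, ion suppression or matrix effects.

**NMR spectra.** Lorentzian lines in the anomeric region: glycogen H1α at
5.41 ppm (2 Hz default width — "broad"), free glucose H1α/H1β doublets at
5.22/4.64 ppm split 1:2 by the anomeric equilibrium (³J_HH 3.8/7.9 Hz), a
9-proton DSS singlet at 0 ppm, and for ¹³C-enriched pools satellite
doublets at ±¹J_CH/2 (default 170 Hz, a literature value for the anomeric
CH — the coupling is configurable because it was not itself measured
here) carrying fraction F of the area. For ²H₇ labeling the anomeric
proton is replaced by deuterium, so labeled molecules drop out of the ¹H
signal — modeled as a proportional loss of visible concentration. Noise is
additive Gaussian with default sd 5×10⁻⁵ of the tallest peak (reference
SNR ≈ 2×10⁴, representative of cryoprobe 1D ¹H acquisitions of mM-level
extracts). A noise floor at a percent-level of the reference apex would
make satellite integrals quantification-limited and is not representative
of the instruments emulated. No FID-level processing (phasing,
apodization), no 2D spectra.

Seeds are mandatory for all synthesis; a missing seed raises instead of
silently producing irreproducible output. Fixed seed ⇒ bit-identical
spectra.

## FTMS quantification

Peak picking (local maxima above an SNR threshold times a MAD-based noise
estimate, 3-point parabolic centroiding) runs for diagnostics, but
quantification itself is a targeted readout: the observed intensity of
each isotopologue channel is the least-squares Gaussian-amplitude
(matched-filter) estimate at the channel's exact mass, using the
instrument's peak-width model. The natural-abundance correction matrix is
built with the same observation model — a fine-structure line at distance
d from a channel contributes its probability attenuated by the
Gaussian-overlap factor exp(−d²/4σ²) — so the linear system C·x = observed
is exactly consistent with how the observations are taken. This matters:
an apex-sample estimator is noise-amplified (noise splits flat peak tops
into several local maxima) and was measurably biased in round-trip tests;
the matched filter is unbiased and recovers isotopologue fractions to
better than 0.005 at default noise.

C is solved directly; condition numbers above 1e8 are an error (that is
the unresolvable-channel regime, e.g. a mixed ¹³C/²H ladder at low
resolving power). Negative solutions are clipped to zero with a warning
when the clipped mass exceeds 1%. Absolute amounts come from the spike
ratio amount_j = spike_nmol · I_j/I_spike; the spike channel is excluded
from analyte totals, and spiking a species that is itself an expected
analyte (¹³C₆ spike in a ¹³C-tracer sample) is rejected with a pointer to
the dual-labeled standard. Mass-match tolerance defaults to 5 ppm
(configurable; synthetic spectra are perfectly calibrated, real data may
need recalibration first). Multiple scans are averaged onto a common axis
before analysis (composite spectrum).

## NMR quantification

Window integrals are trapezoidal after subtracting a linear baseline
through the window edges; each baseline anchor is the mean of the
outermost ~10% of window points (a single noisy endpoint would be
multiplied by the window width and dominate the error budget). Default
windows (halfwidth 0.022 ppm): glycogen H1α 5.41, glucose H1α 5.22, H1β
4.64, DSS 0.00 ppm; satellite windows sit at ±¹J_CH/2 converted to ppm by
the spectrometer frequency (600 MHz default, i.e. 14.1 T). Window sets
refuse to construct if any windows intersect after satellite expansion —
overlapping satellites (e.g. glycogen vs glucose H1α at low field) need 2D
experiments that are out of scope.

Fractional enrichment is F = I(¹³C)/[I(¹³C)+I(¹²C)] per window. Absolute
quantification is referenced to DSS (9 equivalent protons):
conc = DSS_mM · (I/n_protons)/(I_DSS/9). Within the pipeline, glucose
amounts and F are taken from the H1β window: it sits in clean spectral
territory, whereas the H1α window at 5.22 ppm is structurally contaminated
at the ~2% level by the tails of the glycogen lines 0.05–0.19 ppm away
(H1α is still integrated, for the 1:2 anomer-ratio QC). Glucose and
Glc-6-P are reported as one pool, as their anomeric resonances coincide at
this field. Known bias: the broad (2 Hz) glycogen line loses ~5% more of
its area to the finite window + baseline treatment than the 1 Hz DSS
reference does, so NMR glycogen (and hence the NMR-visible fraction) runs
a few percent low; ratios within a lineshape (F, anomer ratio) cancel this
and are accurate to <0.01.

## Pipeline, scenarios, QC

`run_pipeline` follows the wet workflow order: NMR on the intact extract →
hydrolysis (simulated, with the efficiency standard digested at the same
condition) → FTMS and NMR on the hydrolysate → computation chain → report,
QC table and run log. Four bundled scenarios emulate the studied systems
(unlabeled bronchial cells; ¹³C₆-fed tumor-bearing mouse liver at a
46/38/16 unlabeled/direct/scrambled split with 85% NMR-visible glycogen;
paired ²H₇-labeled cancerous/non-cancerous lung slices at ~15% vs ~27%
enrichment). Scenario parameters are the study conditions, fixed once.
Child seeds for the four synthesis stages derive from the run seed via
`SeedSequence`; identical config + seed gives byte-identical JSON reports.
QC checks (never aborting): anomer ratio within 20% of 1:2, spike within
10-fold of the tallest analyte, non-negative net glucose, satellite-window
collisions. The run log contains every numeric parameter used.

File formats: two-column CSV for both modalities; mzML 1.1 read/write for
mass spectra via a small self-contained codec (64/32-bit base64 arrays,
optional zlib, plain or index-wrapped documents) validated by round-trip
tests. Units are fixed globally: Da, nmol, µg/mg; enrichment is a fraction
internally and percent in reports.

## What passing tests do and do not show

The test suite demonstrates that the computation chain is correct on data
whose ground truth is known exactly, at realistic instrument parameters:
enumeration and fine-structure oracles, closed-form resolvability,
hydrolysis-model anchors, worked-example arithmetic, and 100-scenario
end-to-end recovery (isotopologue fractions within 0.01, glycogen mass
within 5%). It does not demonstrate performance on real spectra, which add
baseline roll, chemical noise, calibration drift, ion suppression and
peak-shape deviations that the generator deliberately omits. Problem sizes
(one spectrum per stage, ~10⁴–10⁵ axis points, 100 scenarios) were chosen
as comfortable desk-scale checks of the mathematics, not as instrument
benchmarks.

## Known limitations

- 2D (TOCSY/HSQC) positional isotopomer analysis is out of scope; only 1D
  satellite enrichment is computed, and colliding satellite windows raise
  rather than disentangle.
- The hydrolysis model is an empirical stand-in calibrated to three
  anchors; it should not be extrapolated far outside 80–150 °C.
- The NMR-visible-fraction estimate inherits the few-percent broad-line
  integration bias described above.
- Mass calibration of real FTMS data is assumed good to the 5 ppm match
  tolerance; no recalibration is performed.
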