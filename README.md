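# glycotrace

Micro-scale analysis of glycogen content and turnover by ultra-high
resolution FTMS and ¹H NMR, for stable isotope resolved metabolomics
(SIRM) experiments.

## The problem

Glycogen is the main storage form of glucose in mammals, and its turnover
is informative in liver metabolism, immunology and cancer. Measuring
turnover needs more than a total: after feeding a labeled precursor
(¹³C₆-glucose, ²H₇-glucose), one must quantify **how much** glycogen a
mg-scale sample holds and **which glucose isotopologues** it is built
from. The approach implemented here measures glucose before and after acid
hydrolysis of the extract — intact (NMR-visible) glycogen by ¹H NMR first,
then the full glucose release by direct-infusion FTMS and/or NMR — and
computes:

```
net glucose           = post-hydrolysis − pre-hydrolysis glucose      [nmol]
glycogen              = net glucose / 6.17                            [µg]
corrected glycogen    = glycogen / hydrolysis efficiency              [µg]
content               = corrected glycogen / protein                  [µg/mg]
```

with 6.17 µmol glucose per mg glycogen from the residue mass
180.06 − 18.01 = 162.05 g/mol. On top of the chain it reports the
isotopologue split (unlabeled / fully labeled / scrambled), fractional
enrichment 100·L/(L+U), ¹³C-satellite enrichment from NMR
(F = I(¹³C)/[I(¹³C)+I(¹²C)]), and the NMR-visible fraction of total
glycogen. At resolving powers of 500,000–1,000,000 the 2.9 mDa gap between
¹³C₁- and ²H₁-glucose is cleanly separated, so ¹³C and ²H tracers can be
read out simultaneously from one spectrum.

No raw data from the original experiments are deposited anywhere, so the
package ships a first-class synthetic-data generator (labeling scenarios,
hydrolysis kinetics, FTMS and NMR spectrum synthesis) that makes every
stage testable against known ground truth.

## Layout

- `src/glycotrace/` — the library: `isotopes` (enumeration, exact masses,
  fine structure, resolvability), `synth` (scenario/hydrolysis/spectrum
  generators), `ftms` and `nmr` (quantification), `glycogen` (the
  computation chain), `pipeline` (end-to-end runs, QC, reports),
  `spectra` (CSV/mzML I/O), `scenarios` (bundled study-like conditions).
- `analysis/01…05_*.py` — numbered narrative drivers: hydrolysis
  optimization map, isotopologue resolvability table, unlabeled
  cell-culture quantification, ¹³C₆ mouse-liver labeling, ²H₇ lung-slice
  comparison. Each writes small tables under `results/`.
- `docs/methods.md` — models, parameters, design choices, limitations.

## Worked example

```python
from glycotrace import net_glucose, glycogen_from_glucose

net = net_glucose(140.5, 29.1)          # post, pre (nmol)  -> 111.4
report = glycogen_from_glucose(net, efficiency=0.745)
print(round(report.glycogen_ug, 1))           # 18.1 µg
print(round(report.corrected_glycogen_ug, 1)) # 24.2 µg
```

End to end on synthetic data (`python analysis/04_mouse_liver_13c_labeling.py`):

```
Liver glycogen after 13C6-glucose feeding (simulate mode):
    component  true_percent  measured_percent
    unlabeled          46.3              46.4
fully_labeled          37.6              37.8
    scrambled          16.1              15.8

Total glycogen (corrected): 44.9 ug vs 44.8 ug ground truth.
13C fractional enrichment of hydrolyzed glycogen: 53.6%.
NMR-visible glycogen: 80% of the hydrolysis-determined total ...
```

The pipeline simulated a liver-like sample (44.8 µg glycogen whose
hydrolysate is 46.3% unlabeled, 37.6% fully ¹³C₆-labeled, 16.1% scrambled),
synthesized the four spectra, quantified them against the ¹³C₆,²H₇ spike,
and recovered both the total mass (0.2% off) and the composition (within
0.3 points) — the scrambled ¹³C₁–¹³C₅ ladder reporting pentose-phosphate /
gluconeogenic rearrangement.

Programmatic runs use `RunConfig`/`run_pipeline` with `mode="simulate"`
(bundled or custom scenario + seed) or `mode="analyze"` (mzML/CSV spectra
from disk).

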