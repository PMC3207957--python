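# cardiot1

Quantitative cardiac T1-mapping analysis for contrast-enhanced studies of
murine myocardial infarction: from multi-flip-angle magnitude images to
regional ΔR1, wall-thickening-based tissue classification, and an estimate
of the effective in vivo relaxivity of the contrast agent.

## Who this is for

Small-animal cardiac MR groups quantifying the accumulation of a
T1-shortening (e.g. Gd-based liposomal) contrast agent in infarcted
myocardium.  Signal intensity alone is a poor concentration read-out —
coil sensitivity, gain and sequence timing all confound it — so the
analysis works on relaxation rates instead: R1 = 1/T1 rises linearly with
local agent concentration,

    R1 = R1,0 + r1 · [CA],

with relaxivity r1 in mM⁻¹s⁻¹.  Comparing pre- and post-contrast R1 maps
segment by segment gives ΔR1 = R1ᵖᵒˢᵗ − R1ᵖʳᵉ, which is proportional to
the regional agent concentration.

## What the package computes

* **T1/R1 maps** — spoiled gradient-echo (SPGR) forward model; voxelwise
  variable-flip-angle (VFA/DESPOT1) fitting with bounded nonlinear
  refinement; inversion-recovery snapshot-FLASH fitting of
  |A − B·exp(−TI/T1\*)| with Look-Locker correction T1 = T1\*(B/A − 1).
* **AHA 17-segment geometry** — segment labels anchored at the anterior RV
  insertion; per-segment wall thickness by radial ray casting at
  end-diastole and end-systole; systolic wall thickening
  SWT = (WTᴱˢ/WTᴱᴰ − 1)·100%, with segments classified infarct
  (SWT < 15%), remote (SWT > 45%) or intermediate.
* **Regional quantification** — per-segment mean R1 and ΔR1; conversion of
  ex vivo Gd masses to concentration via the myocardial specific gravity
  (1.05 g/ml) and the Gd molar mass (157.25 g/mol); Pearson correlation
  per segment and per slice; Deming (orthogonal, errors-in-variables)
  regression of ΔR1 on [Gd] whose slope is the effective in vivo r1;
  one-way ANOVA + Tukey HSD on R1 values across tissue classes.
* **Digital heart phantom** — an annular LV with an anterolateral infarct
  sector (elevated pre-contrast T1, concentrated Gd, depressed
  thickening), Rician-noise SPGR/IR image synthesis, and a virtual ICP-MS
  sectioner, so the whole chain is testable against known truth.

## Worked example

```bash
python examples/03_ir_relaxivity_calibration.py
```

prints (seeded run):

```
relaxivity r1 = 2.186 mM^-1 s^-1  (generator 2.2)
baseline R1   = 0.353 1/s          (generator 0.35)
R^2 = 0.9999
```

i.e. fitting 10 simulated calibration tubes (60 inversion times,
72–4792 ms, SNR 100) and regressing fitted R1 on concentration recovers
the generator relaxivity to within 1%.  The full chain,

```bash
python examples/05_full_pipeline.py     # or: cardiot1 run --seed 11 --out run/
```

simulates the phantom, fits pre/post R1 maps, builds the regional table
and fits the Deming regression, ending with

```
Deming slope = 1.095 mM^-1 s^-1 (phantom truth 1.06),  r = 0.996
```

— the slope of ΔR1 against sector Gd concentration is the effective
in vivo relaxivity, recovered here within ~3% of the phantom's ground
truth.  The other examples cover the phantom itself, VFA fitting and the
AHA wall-thickening table; each prints the numbers it computes and what
they mean.

A thin CLI mirrors the stages: `cardiot1 simulate | fit-t1 | segment |
quantify | correlate | run` (see `cardiot1 --help`).

## Layout

```
src/cardiot1/     phantom, relaxometry, geometry, quantify, pipeline, io, cli
examples/         one narrative script per capability
tests/            unit, property and end-to-end suites
docs/methods.md   models, assumptions, parameter choices, limitations
```
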