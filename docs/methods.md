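# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `cardiot1`.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Relaxation models

**SPGR / variable flip angle.**  The spoiled gradient-echo steady state is

S(α) = M₀ sin α (1 − E₁)/(1 − E₁ cos α),  E₁ = exp(−TR/T1).

With ≥ 2 flip angles at fixed TR, (T1, M₀) are identifiable.  The fit
(`fit_t1_vfa`) first solves the linearized DESPOT1 form — regress S/sin α
on S/tan α, slope = E₁ — and uses it to initialize a bounded nonlinear
least-squares fit of the closed form (T1 ∈ [100, 6000] ms, parameter
tolerance 1e-10, ≤ 200 function evaluations).  The linearized solution
alone is noise-fragile with only three angles; the refinement is what the
tests exercise.  Voxels that are all zero, non-finite, or whose refined T1
pins at a bound are dropped from `valid_mask` rather than raising.

*Magnitude bias.*  Magnitude MR images carry Rician noise.  The fitter
treats magnitudes as Gaussian observations, which is accurate for
per-image SNR ≳ 10.  At TR = 10 ms the SPGR signals at 2/8/14° are only
3–7% of M₀, so an M₀-referenced SNR of 50 means per-image SNR 1.6–3.5;
there the noise floor biases T1 upward by several per cent (measured
median +6% in the Monte-Carlo test) and no per-voxel estimator does much
better — we tried a second-moment noise-floor correction and a
Rician-mean forward model, both of which overcorrect in this regime.  The
practical answer is acquisition averaging, which the phantom's default
noise level represents (see below).

**Inversion-recovery snapshot-FLASH.**  Each tube/voxel recovery is fitted
with the three-parameter magnitude model |A − B·exp(−TI/T1*)|.  Polarity
restoration handles the magnitude bias deterministically: candidate
sign-flip positions around the signal minimum are tried and the best
residual wins (chosen over complex-valued fitting because only magnitudes
exist).  The segmented low-flip readout drives recovery at the apparent
rate 1/T1* = 1/T1 − ln(cos α)/(TR·N_seg); the standard Look-Locker
correction T1 = T1*(B/A − 1) inverts this exactly for ideal inversion
(B = A + M₀) and can be disabled for conventional IR data.  The generator
and the fitter share only the algebraic model, not code paths, and the
round trip is exact to 1e-6 relative on noiseless series.

**Rates and ΔR1.**  R1 = 1000/T1(ms) in s⁻¹; the conversion is a single
involution (`r1_map`).  Regional ΔR1 is the **difference of segment-mean
R1 values**, not the mean of voxelwise differences; the two differ under
Jensen-type averaging when the intra-segment distribution changes between
scans, and the segment-mean convention also removes any need for
voxelwise pre/post registration across the 24 h interval — correspondence
is at segment level through the AHA labels.

**Calibration.**  In vitro relaxivity is ordinary least squares of R1 on
concentration: concentration is the controlled variable in a tube
experiment, so errors-in-variables machinery is unnecessary there.

## Deming (orthogonal) regression

For the in vivo comparison both axes carry error (CMR-derived ΔR1;
ICP-MS-derived [Gd] with cutting misalignment), so the slope comes from
the Deming estimator with error-variance ratio λ = Var(εy)/Var(εx):

β = [s_yy − λ·s_xx + √((s_yy − λ·s_xx)² + 4λ·s_xy²)] / (2·s_xy).

λ = 1 (classical orthogonal/total least squares on the raw scales) is the
default: the two measurement variances are not separately known, and the
fitted slope cannot pin λ down.  λ → ∞ reproduces OLS of y on x, which
the tests verify to 1e-6; the λ = 1 fit is symmetric under (x, y)
exchange and never smaller in magnitude than OLS (attenuation ordering).
Degenerate clouds (s_xy = 0 with s_yy = λ·s_xx) are reported as such, not
guessed.  95% confidence intervals use a leave-one-out jackknife with a
t critical value on n − 1 degrees of freedom; the intercept CI excluding
zero is the package's offset-significance test.  `scipy.odr` serves as an
independent cross-check of the estimator in the test suite.

## AHA geometry

Angle convention: short-axis slices viewed from the apex, angles
counterclockwise, 0° at the anterior RV-insertion anchor (supplied by
config; the phantom provides its truth value).  Basal and mid levels are
six 60° sectors ordered anterior → anteroseptal → inferoseptal → inferior
→ inferolateral → anterolateral; the apical level is four 90° sectors
centred on the cardinal walls; the most apical slice(s) without blood
pool form segment 17.  Slices containing blood pool are split base→apex
into equal thirds by slice count, remainder assigned basally (the level
assignment is otherwise underdetermined by short-axis data).  "Posterior"
in the four-sector ex vivo cutting nomenclature maps to AHA "inferior".

**Wall thickness** is measured per slice by casting 360 rays (default)
from the slice center — blood-pool centroid where present, enclosed-cavity
centroid otherwise; slices whose myocardium leaves an angular gap
(crescents) are flagged and excluded.  Thickness along a ray is the chord
from endocardial entry to epicardial exit, sampled at a quarter-voxel
step with nearest-voxel lookup; a segment's WT is the mean over all rays
landing in its angular span across its slices (mean-over-rays chosen over
a single mid-segment chord; with < 3 rays the segment is flagged).  The
2D-per-slice ray casting matches short-axis acquisitions; it is not a 3D
centerline-normal measurement.  SWT = (WTᴱˢ/WTᴱᴰ − 1)·100% exactly;
WTᴱᴰ = 0 propagates as missing rather than dividing.

**Ex vivo sectors.**  The four cutting sectors are 90° spans relative to
the anchor (anterior centred on it).  Aggregating mid-level AHA segments
into sectors weights each segment by voxel count × angular overlap; for
piecewise-constant fields whose boundaries align with segment boundaries
this reproduces the true sector means exactly.

## The phantom and what it does (not) emulate

The phantom is a stack of short-axis slices on a 64×64×12 grid of
0.1×0.1×0.5 mm voxels: 10 LV slices, the most apical one a solid disk,
the rest annuli (ED endocardial/epicardial radii 1.0/1.8 mm — a 0.8 mm
wall).  Remote tissue thickens to 1.32 mm at ES (SWT 65%, the healthy
murine value); an angular lesion sector (default 90° centred
anterolaterally, matching where reperfusion infarcts typically sit)
thickens by ED·(1 + 0.65·f) with f = 0.1 by default, i.e. SWT 6.5%,
safely in the infarct class.  Tissue values are piecewise constant so
regional statistics have exact truths: pre-contrast T1 2030 ms (lesion) /
1761 ms (remote) / 2300 ms (blood); Gd 0.566 mM in the lesion and
0.142 mM background (residual circulating agent), chosen so that at the
default true relaxivity 1.06 mM⁻¹s⁻¹ the lesion and remote ΔR1 sit at
0.60 and 0.15 s⁻¹ — the regimes the analysis is meant to distinguish.
Post-contrast T1 follows R1ᵖᵒˢᵗ = R1ᵖʳᵉ + r1·[Gd] voxelwise.

Acquisition defaults: TR = 10 ms, flip angles 2/8/14°, bright- or
black-blood synthesis (black-blood zeroes the blood signal, as used for
wall delineation); noise is Rician — the magnitude of the signal plus
complex Gaussian noise — at a default σ of 0.5% of M₀, representing a
heavily averaged 20-minute 3D acquisition (per-image SNR ≈ 6–14 on the
SPGR signals, where the magnitude fit's bias is below 1%).  The virtual
ICP-MS sectioner cuts the slice 2.5 mm above the apex into four angular
sectors and integrates tissue mass (×1.05 g/ml) and Gd mass
(×157.25 g/mol); its `cut_angle_offset_deg` emulates the angular
misalignment of physical cutting, which degrades per-segment correlation
while per-slice averages survive — the mechanism the correlation tests
reproduce.

Not modelled: cardiac motion beyond the two ED/ES geometries (full CINE
is out of scope), surface-coil intensity gradients (acknowledged but
unquantified in the source protocol; inventing parameters would test
nothing), B1/slice-profile errors on the flip angles, partial-volume
mixtures at tissue boundaries beyond voxelization, water exchange and
compartmentalization of the agent.  Passing tests therefore demonstrate
correctness of the estimators and geometry on idealized anatomy, not
robustness to those real-data effects; the in-vivo/in-vitro relaxivity
gap itself (compartmentalization) is an input to the phantom, not a
phenomenon it explains.

## Degenerate inputs and tie-breaks

Zero-contrast runs make all sector concentrations equal; the correlate
stage reports the regression as degenerate instead of fitting a slope.
All-zero voxels and rays missing the myocardium are excluded, never
fatal.  Classification uses strict inequalities, so SWT exactly 15% or
45% is intermediate.  Sign restoration in the IR fit tries flip positions
around the |signal| minimum, which resolves the null-point sample's
ambiguous polarity exactly in the noiseless limit.

## Problem sizes

The default test/demonstration sizes — 64×64×12 grid, ~10⁴ fitted voxels
per contrast, 500-replicate Monte-Carlo loops, 10⁴-replicate ANOVA
calibration — were chosen so the full suite and the acceptance script
each run in a few minutes on one core while leaving every statistical
check comfortably powered.
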