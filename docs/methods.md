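# Methods

## SUV model

SUV is computed as activity concentration (Bq/ml) times a subject factor
N / D(t_scan), where D is the injected activity decayed physically to scan
start with the ¹⁸F half-life (109.77 min) and N is the normaliser:

* **BW** — body weight in grams: the conventional dimensionless SUV;
* **LBM** — Janmahasatian sex-specific lean body mass in grams
  (male 9270·W/(6680+216·BMI), female 9270·W/(8780+244·BMI));
* **BSA** — DuBois surface area (0.007184·W^0.425·(100·H)^0.725) in cm²,
  which puts SUV on a ~0.05 scale rather than ~2.

These particular LBM/BSA equations are the prevailing nuclear-medicine
choices; vendor consoles differ, which is the main reason absolute
SUV(LBM)/SUV(BSA) values are not transportable across sites. Decaying the
dose to scan start rather than mid-scan is the standard convention for a
single whole-body pass; the two decay conventions (dose decayed forward vs
image decay-corrected back) are algebraically identical and asserted so in
the tests. A BMI ≥ 12 guard protects the LBM formula's validity range; the
male formula's LBM = W crossing sits just below that guard, so the algebra
is tested at the boundary instead of the root. An optional multiplicative
plasma-glucose correction to 5.0 mmol/l is provided but off by default:
the study protocol corrected for pre-scan glucose, but no formula is
standard, and the correction cancels in TBR anyway.

## Regional statistics

All masks and images live on axis-aligned voxel grids compared in world
(mm) space, voxel-center convention, 0-based indices. Rebinning between
PET (4×4×4 mm) and CT (1.17×1.17×4 mm) grids uses nearest-neighbour or
trilinear interpolation with 0-fill outside the source extent; masks are
always transferred nearest-neighbour (preserves binarity without a
threshold), and a transfer that empties a mask is an error, not a silent
empty region.

The three SUVmax readings: WS is the max over the full VOI; HS is the max
on the hottest axial slice (automated HS picks the argmax slice, so
HS = WS exactly; an observer override models the visual pick and can only
be ≤ WS); MDS averages the per-slice maxima over the hot slice and its two
neighbours, dropping neighbours outside the VOI, so MDS ≤ HS always holds
at the automated center — averaging more slices is exactly why MDS reads
lower. Hot-slice ties break toward the lowest z for determinism.

Blood-pool SUVmean requires ≥ 3 axial slices and optionally erodes the
mask by one voxel to suppress wall spill-in (off by default, mirroring
ROIs drawn in the vessel center). TBR divides a wall SUVmax by a
background SUVmean — by default the mean of the available vena-cava
measurements, configurable to the ascending-aorta blood pool.

## Agreement statistics

ICC(2,1) — single-measure, two-way random effects, absolute agreement — is
computed from the two-way ANOVA mean squares, with the McGraw–Wong
Satterthwaite F interval for the 95% CI; a zero-variance matrix is perfect
agreement by definition (estimate 1, degenerate CI, flagged). Single
measures (not average-measure ICC) because single observers/methods are
compared. Bland–Altman reports bias ± 1.96·SD of the paired differences,
with the proportional-bias rule: if pair means correlate with pair
differences (Pearson, α = 0.05) the series are ln-transformed first.
Levene's test is the classic mean-centered variant. Complete-case handling
throughout, with dropped-row counts in every result.

The uptake-time model is outcome ~ time (minutes) with a per-patient
random intercept and slope and a per-segment random intercept, fitted by
REML via statsmodels MixedLM. The segment intercept enters as a variance
component nested within patient — statsmodels supports one grouping level,
and in this design every segment is measured within every patient, so the
nested fit matches the data layout. Inference on the fixed slope uses a
t reference with between-patient degrees of freedom (n_patients − 1):
with six patients the slope information is patient-level and the
normal-based Wald interval undercovers badly (≈87% empirical coverage vs
≈95% with the t interval in the recovery simulations). Non-convergence
falls back to a random-intercept-only fit, flagged in the result. Time can
alternatively be coded as a 3-level factor; the headline coefficient then
becomes the last-level contrast.

## Phantom generator

The voxel phantom is an axis-aligned cylindrical vessel (lumen radius
12 mm, wall 6 mm) in a 64×64×48 grid at 4 mm, with mono-exponential
biological clearance per compartment from injection. The paper-like preset
uses wall SUV₀ 1.45 with a 550-min biological half-life, blood SUV₀ 1.45
with 140 min, a ×1.5 focal lesion over three slices, 7 mm FWHM Gaussian
PSF (typical clinical PET, reflective boundaries so total counts are
conserved), and additive Gaussian noise (SD 0.05 SUV, clipped at zero) —
a standard approximation for post-reconstruction image noise. These
constants were chosen so the simulated SUVmax and TBRmax at 38/60/90 min
sit near the study cohort's group means (SUVmax ≈1.75→1.64, TBRmax
≈1.30→1.57) with blood clearing faster than wall; they are defaults, not
fits, and every acceptance property (orderings, directions, rebinning
neutrality) is independent of their exact values.

What the phantom does *not* emulate: Poisson emission statistics and
reconstruction (TOF-OSEM), attenuation/scatter, patient motion, anatomy
beyond a straight tube, and calcification. Passing phantom tests therefore
demonstrates correctness of the measurement chain and the direction of
kinetic effects, not clinical accuracy on real scans.

The tabular cohort simulator draws from an explicit mixed-effects model
(defaults: 6 patients, 10 arterial segments, 38/60/90 min, slope
0.0047 SUV/min ≈ 0.28 per hour, patient intercept SD 0.19, patient slope
SD 0.002/min, segment SD 0.15, residual SD 0.15, two observers with error
SD 0.10) so that the statistics layer can be validated against known
generating parameters, including the closed-form ICC
σ²_true/(σ²_true+σ²_err).

## Problem sizes and numerical choices

Phantom batches use 10–50 seeds and the recovery simulations 50–200
simulated cohorts; at these sizes the mixed-model recovery has ~1.5%
binomial error on coverage, and the full suite plus the acceptance script
run in a few minutes on one CPU. Exact-equality assertions (NEAREST
rebinning, HS = WS) are genuinely exact — value copies, not
interpolations. Floating-point comparisons elsewhere use explicit
tolerances stated in the tests.

## Known limitations

* No DICOM ingestion or PET–CT registration (assumed pre-aligned).
* Crossed random effects are unavailable in statsmodels; the per-segment
  intercept is nested within patient (identical layout for this design).
* The deposited per-patient table of the original study is an SPSS .sav
  file; ingestion is via CSV export plus a column-mapping file, since the
  internal column names are undocumented.
* Partial-volume correction and automatic spill-over handling are out of
  scope; spill-over is handled only by VOI editing.
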