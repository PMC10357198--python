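# Methods

## The measurement pipeline

### Oscillatory shear

A record at angular frequency ω is the pair γ(t) = γ₀ sin(ωt),
τ(t) = γ₀[G′ sin(ωt) + G″ cos(ωt)] + noise. Moduli are extracted by linear
least squares on the design [sin ωt, cos ωt, 1]; the constant column absorbs
transducer drift, so an offset never biases G′ or G″. The fit is exact (to
machine precision) on noiseless single-tone input at any phase, and under
Gaussian noise of relative SD s the modulus error scales as s/√N with N
samples. A record must span ≥3 full cycles; a >1% RMS mismatch between the
strain channel and γ₀ sin(ωt) raises a frequency-mismatch warning rather
than an error, since the stress fit may still be usable. δ is reported in
degrees (the field convention); |G\*|² = G′² + G″² holds to 1e-9 relative by
construction. Instrument geometry (8 mm biopsy, 12 mm plate, 2 mm gap) is
carried as metadata only: stress arrives already reduced to Pa, as no
raw-torque pipeline is defined for these data. Sweep summaries average
arithmetically over a frequency band (default the full 1–40 rad/s ladder)
and read δ at the ladder points nearest the requested frequencies.

### Compression

"True stress" is interpreted as force over the current cross-section of an
incompressible cylinder, σ = F(1−ε)/A₀, with ε = u/h₀ the engineering
compression — consistent with pairing true stress with percent strains up to
40–60%. Both σ and ε are positive in compression. The instantaneous modulus
uses the 5-point centered stencil (exact through quartics) on the interior
and 2nd-order one-sided 3-point stencils at the two points of each end, so
output length equals input length. The stencil requires uniform strain
spacing (relative tolerance 1e-6); non-uniform recordings are linearly
resampled first (default resolution 0.5% strain). Windowed moduli are OLS
slopes over closed strain windows and need ≥3 points. Contact/indentation
corrections for the chamfered tip are out of scope: loading is treated as
uniform uniaxial over the sample area (the probe-vs-sample area choice is a
single diameter parameter).

### Elastin assay

Calibration is ordinary least squares A₅₁₃ = slope·mass + intercept over ≥3
distinct standard levels; the intercept absorbs the reagent blank (the kit's
curve is treated as linear — no sigmoidal behavior is modelled). A
non-positive slope is a calibration failure. Sample mass is
(A − intercept)/slope, clamped at zero with a warning below the blank, then
normalized by tissue wet mass. The skin-control gate "around the expected
3.5 μg/mg" is quantified as ±20% relative tolerance, configurable, since no
numeric band is published.

### Histology

Area fractions count positive pixel centers inside the ROI polygon over all
centers inside it. Containment uses the polygon's closed region via shapely
(`intersects_xy`), so a center exactly on an edge counts inside; for the
simple polygons required this equals the even-odd rule. No particle-size or
circularity filters are applied. Binarization/leveling of raw micrographs is
upstream of this package: inputs are already 0/255 masks. Background
correction subtracts the same-slide negative control's fraction, clamped at
zero; dermis-relative values are 100·fraction/dermis_fraction. Section
profiles average technical replicates within each of the four section types
(cross, inner, middle, outer tangential).

### Statistics

Aggregation is strictly two-level: technical replicates average to animal
means; group mean and SD (n−1 denominator) and all tests use animal means
only. Student's pooled-variance t-test is the headline two-group test
(chosen because it is the study's named test, despite unequal n of 5 vs 2);
Welch's form is available behind a flag. One-factor ANOVA pairs with
Tukey–Kramer adjusted comparisons (scipy's studentized-range implementation,
which uses Kramer's unequal-n standard errors). Two-factor ANOVA (group ×
frequency-level designs) uses Type II sums of squares with interaction via
statsmodels, degenerating to one-factor when the second factor has a single
level; a factor combination with no observations is rejected. Star labels
are a pure threshold function of p. No multiple-testing correction is
applied across summary-table rows (none is applied in the study design this
mirrors).

## The capsule compression model

### Constitutive content

The capsule is a nearly incompressible neo-Hookean solid reinforced by two
linear-elastic fiber families with single-branch generalized-Maxwell
viscoelasticity. The matrix uniaxial Cauchy stress is the incompressible
closed form σ_m = μ(λ² − λ⁻¹), μ = E_m/2(1+ν), with the pressure eliminated
by traction-free lateral faces. ν = 0.4999 is honored inside μ while the
kinematics use exact incompressibility; the resulting 0.02% discrepancy
between 3μ and E_m is accepted and documented (the initial tangent is
295.06 kPa for E_m = 295 kPa).

Each fiber family carries stress on its engineering strain (quadratic
energy; fibers support compression, per the linear-elastic reading). The
axial family sees e_ax = λ − 1. The tangential family is one in-plane family
at the lateral stretch λ_t = λ^(−1/2) of the incompressible kinematics
(azimuthal vs radial cannot be resolved from a 1D model); its tension enters
the axial stress through the kinematic coupling λ·(dλ_t/dλ) = −½λ^(−1/2), so
tangential fibers stiffen compression as they resist lateral spread.

Viscoelasticity is an equilibrium spring of stiffness (1−f_e)E_f in parallel
with a Maxwell branch of stiffness f_e·E_f and relaxation time t_r,
integrated by implicit Euler: e_v ← (e_v + Δe_f)/(1 + dt/t_r),
s_f = E_f[(1−f_e)e_f + f_e·e_v]. A step-and-hold history relaxes by exactly
the fraction f_e, which is how the "energy factor" normalization is read
(branch stiffness = f_e·E_f); defaults f_e = 2%, t_r = 50 s.

### Layering and the solver

The thickness divides into in/mid/out thirds, with axial fibers confined to
the inner `axial_zone` = 4/9 of the thickness (the inner zone plus the inner
third of the mid zone). Zone boundaries are augmented by the axial-zone
boundary when needed, yielding by default four layers (1/3, 1/9, 2/9, 1/3)
with r_v_ax = axial_fold · r_v_tan in the first two. Because the layers are
in series under uniaxial load, a rigid platen at constant speed imposes, at
each time step, equal axial stress across layers and layer compressions
summing to the imposed displacement. The step is solved by an outer Newton
iteration on the common stress with an inner Newton inversion of each
layer's (strictly monotone) stress–stretch relation; tolerances are 1e-12 on
the strain residual with at most 50 outer iterations, and non-convergence
halves dt and restarts (≤3 times). The default dt is min(t_r/10,
loading_time/200), i.e. 200 steps over the 13.2 s ramp to 40% strain at
0.1 mm/s for a 3.3 mm specimen — halving dt moves σ(40%) by far less than
0.1%. This 1D series-layer homogenization deliberately replaces a 3D
contact finite-element treatment: the constitutive law, parameter values and
the fitted-fold conclusions are the transferable science, while indenter
contact geometry and mesh-level stress fields are not specified tightly
enough to re-derive and add nothing to the fold/volume-fraction inference.
Series homogenization is exact here, so refining the layering leaves the
curve unchanged to 1e-6 — a property the tests exercise.

Densities (1.05, 1.2 g/mL) are carried on the parameter object for fidelity
but unused: at 0.1 mm/s inertia is negligible and the solve is quasi-static.

### Fitting

`fit_sweep` enumerates a grid over (E_m, r_v_tan, axial_fold), simulates
each point, resamples onto the observed strain grid and scores
r² = 1 − SS_res/SS_tot. Ties break toward smaller axial_fold, then smaller
r_v_tan (enumeration order plus strictly-greater replacement), so degenerate
plateaus prefer the simpler fiber architecture. On noiseless self-generated
curves the sweep recovers the generating triple exactly (r² = 1); with 2%
multiplicative stress noise on 80 points the best r² is ≈99.8%, comfortably
above the ~99% regime reported for model-vs-experiment agreement.

## The synthetic cohort generator

The generator emulates the study conditions: two fibrous-capsule groups
(n=5 and n=2 animals), adipose (n=4), skin and dermis controls, three
technical replicates per animal. Between-animal variation is moment-matched
lognormal (strictly positive quantities keep their configured arithmetic
mean and SD exactly); measurement noise is Gaussian. All randomness derives
from one root seed by stable SHA-256 hashing of (group, animal, replicate,
purpose), so cohorts are bit-reproducible and adding a new draw never
perturbs existing ones.

Paper-anchored defaults (used verbatim): G″ 541±54 / 390±40 Pa, E_high
2042±442 / 1043±507 kPa, elastin 3.15±0.90 / 1.92±0.33 μg/mg, cross
13.2±1.1 / 8.6±2.2 %, mid-tangential 12.6±2.2 / 6.2±1.6 %, thickness
4.0±1.1 / 3.3±0.5 mm, skin 3.5 μg/mg, high-strain δ spread 49–67°. The
dermis references are derived from the published dermis-relative ratios
(cross: 13.2/1.49 = 8.86%, mid: 12.6/1.43 = 8.81%).

Non-anchored defaults, chosen once as field-plausible values respecting the
published orderings, and not revisited: low-strain moduli E_low (120/100/20
kPa — only figure-level information exists), all adipose targets (|G\*|
above fibrous tissue via a ×3 dynamic multiplier, E below fibrous, elastin
0.5±0.2 μg/mg), inner/outer tangential area fractions, dermis and
ECM-envelope SDs, assay calibration slope 0.02 A/μg and blank 0.05 A, tissue
masses 8–12 mg, and the noise levels (2% waveform and stress, 0.005 A
absorbance, 0.1pp background jitter). The loss-modulus spectrum uses a weak
power law G″ = B·ω^0.1 (near-flat parallel log–log spectra); because the
per-animal prefactor is normalized by the ladder mean of ω^b, the
sweep-averaged G″ equals the animal's draw for any exponent, which also
makes the "sweep-average vs single-frequency" reading immaterial. Low-strain
δ defaults to 33° (only δ < 45° is published).

Compression curves integrate the tangent-modulus ramp analytically
(E_low + (E_high−E_low)·smoothstep between 10% and 30% strain), so the 0–10%
and 30–40% window slopes equal E_low and the animal's E_high exactly on
noiseless data. Section masks stamp randomly oriented elongated strokes
(aspect ≈10) until the in-ROI positive fraction is within ±0.15pp of the
animal's target plus slide background, shrinking strokes that would
overshoot; the negative control targets the background alone, so the
analysis-side subtraction recovers the configured fraction by construction.

What the generator does **not** emulate: realistic histology textures,
hematoma/staining artifacts, 3D mask stacks, rheometer inertia and LAOS
harmonics, preconditioning/hysteresis in compression, and any within-slide
spatial correlation of signal. Passing tests therefore demonstrate that the
analysis stages are correct inverses of well-specified measurement models at
the study's noise scales — not that they are robust to every artifact of
real instruments or stains.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's own sample sizes (5/2/4
animals × 3 replicates), with Monte-Carlo checks at 200–1000 draws, 256×256
masks, 20 cohort seeds for pipeline recoveries, 50 seeds for the noisy
self-fit, and 200 seeds for the two-factor ANOVA null calibration — sizes
chosen so each claim is statistically meaningful while a full run stays in
the minutes range on one core. Stochastic recovery checks assert the
seed-averaged pipeline value within two single-cohort standard errors of the
configured target; the two-sided KS test at α = 0.01 gates the null
calibration.

Known limitations: the model is 1D and cannot produce stress fields or
contact effects; fiber families are two (axial/tangential) with no dispersed
orientation; the Maxwell update is first-order in dt (adequate since
loading time ≪ t_r at the study rate); Tukey–Kramer power is intrinsically
poor for an n=2 group against a high-variance companion group, so the
small-group-vs-adipose contrast is reported with Student's t.
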