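# Methods

## Signal model and inversion

The package models the steady-state spoiled-gradient-echo (SPGR/FLASH)
signal

SI(α) = M0 · sin α · (1 − E1) / (1 − cos α · E1), with E1 = exp(−TR/T1),

assuming ideal spoiling, TE ≪ T2\* (no T2\*/TE weighting is modeled), and
a steady state reached before readout. T1 and TR are in milliseconds;
flip angles are degrees at every API surface and converted to radians
internally, because both scanner consoles and DICOM report degrees.

T1 and M0 are recovered from exactly two flip angles by the DESPOT1
linearization: with y = SI/sin α and x = SI/tan α, the two points lie on a
line of slope E1, so T1 = −TR/ln(slope) and M0 = (y − slope·x)/(1 − slope).
With two angles the closed form and a least-squares fit coincide, so the
closed form is used — it is exact, vectorizes over whole images, and has
no iteration or starting-value behavior to document.

Invalid-pixel convention: a pixel is flagged invalid (NaN, `valid=False`)
when the two linearized points coincide (e.g. zero signal in air), when
the slope falls outside (0, 1) (noise or inflow can produce negative or
super-unity slopes whose logarithm would give negative or infinite T1),
or when the fitted T1 leaves the plausibility window **1–5000 ms**
(generous bounds around the 200–1400 ms range over which the method is
validated at 1.5 T). Out-of-window fits are discarded rather than clamped
so that downstream statistics are never contaminated by boundary values.
Validity masks propagate: the RR map is valid only where both T1 maps are.

The Ernst angle arccos(E1) maximizes SI at fixed TR/T1. For protocol
design, `optimal_fa_pair` returns the two angles at which the signal
falls to 71 % of the Ernst-angle signal — the standard precision-optimal
dual-angle choice for a narrow T1 range. The two roots are bracketed by
the Ernst angle (the signal is monotone on each branch) and found by
bisection to 1e-8 degrees; bisection is derivative-free and cannot leave
the bracket. The protocol defaults used throughout (TR 5 ms; 5°/15°
pre-contrast, 5°/20° post-contrast) are the published acquisition
settings for liver at 1.5 T and do not exactly satisfy the 71 % criterion
for every liver T1; the optimizer is a design tool, not a constraint.

## Reduction rate

RR% = 100 (T1_pre − T1_post)/T1_pre measures the fractional T1 shortening
produced by hepatocyte uptake of Gd-EOB-DTPA in the hepatobiliary phase.
Its purpose is error cancellation: a multiplicative flip-angle error b
(transmit-B1 inhomogeneity) biases the fitted T1 by roughly 1/b² — up to
tens of percent for b ≈ 1.1 — but the bias factor is nearly T1-independent,
so it divides out of the ratio. The residual second-order RR error is a
few tenths of a percentage point in simulation (see the acceptance
script's `sim_b1_*` outputs). No B1 mapping or correction is implemented;
the simulator only *injects* B1 error so the cancellation is testable.
Pre/post image pairs are assumed co-registered (breath-hold protocol);
geometry mismatches are a hard error, never silently resampled.

## Smoothing

Signal-intensity images are smoothed **before** inversion (the noise then
enters the fit with smaller variance and the nonlinear inversion is
applied to cleaner data), with a normalized 4×4-pixel kernel: Gaussian
with σ = kernel/4 = 1 px sampled on the 4×4 support (default), or a
uniform boxcar. An even kernel has no central sample, so the output pixel
is aligned with the top-left element of the central 2×2 block — an
arbitrary but fixed half-pixel convention, identical for pre and post
images, hence irrelevant to RR. Boundaries are handled by edge
replication, which avoids dark halos at the phantom edge. Constant images
are exact fixed points; region interiors more than the kernel width from
a boundary are untouched in value.

## Digital phantom

`PhantomSpec` renders a cylindrical QA phantom: 208×256 matrix at
1.5×1.5 mm, cylinder radius 90 mm filled with a background solution
(T1 500 ms, M0 800 — arbitrary but plausible filler values), and up to 12
tube slots (20 mm diameter, M0 1000) equally spaced on a ring at 0.7× the
cylinder radius, slot 1 at 12 o'clock, numbered clockwise. The published
slot layout is pictorial only; any declared layout suffices for
validation, and this one is symmetric and collision-free. Region
membership is decided at pixel centers (binary masks; no sub-pixel
partial-volume rendering). The RR validation layout places certified
pairs 657/325 ms in slots 1 and 12, 1264/487 in 2 and 11, 657/328 in 4
and 9, and 813/500 in 6 and 7; the certified values are taken as exact
(their uncertainty is not published).

Noise is Rician: each of the `averages` (default 5) excitations receives
independent complex Gaussian noise of standard deviation `noise_sigma`
(in M0 units) per channel; the complex samples are averaged and the
magnitude taken. Zero-signal pixels are therefore exactly Rayleigh with
scale σ/√averages, which the test suite verifies by a Kolmogorov–Smirnov
test. Stochastic tests use σ equal to 1–2 % of the peak noiseless signal
(SNR ≈ 50–100 at the 5° acquisition), a deliberately conservative stand-in
for a modern phased-array liver acquisition.

The optional B1 error field is b(r) = 1 + a·(r/R)², default a = 0.08 — a
smooth, center-symmetric model of the space-related systematic error of a
body coil. At the slot ring (r = 0.7 R) the effective flip-angle scale is
≈ 1.04, biasing fitted T1 by ≈ 8 %.

`AbdomenFixtureSpec` adds an elliptical body, an elliptical liver region
with distinct pre/post T1 (defaults 657/325 ms), and three certified
reference tubes on the abdominal surface whose T1 is identical in both
phases, so their true RR is zero — the in vivo QA condition that the
measurement process has not drifted (tube stability within 5 % of the
certified value between the start and end of an examination).

What the simulator does **not** emulate: k-space sampling, imperfect
spoiling, motion/ghosting, fat and iron confounders, partial-volume
edges, coil sensitivity profiles, or temperature drift of the certified
tubes (monitored and stable on the real bench). Passing the in-silico
validation therefore demonstrates correctness of the *processing chain*
and the first-order B1 cancellation of RR, not scanner-grade accuracy.

## ROI analysis and validation arithmetic

A pixel belongs to a circular ROI iff its center lies inside the circle;
free-hand ROIs are polygons with point-in-polygon membership at pixel
centers, and ImageJ XY-coordinate exports can be imported directly.
Statistics (mean, SD, median) are computed over valid pixels only, and an
ROI with under 50 % valid pixels (configurable) is an error rather than a
silently thinner sample. The phantom protocol measures a 10 mm ROI
centered in each 20 mm tube, leaving a ≥ 3-pixel guard ring so filter
edge effects cannot reach the ROI; the in-silico in vivo protocol uses
20 mm circles, and per-patient RR is the mean of three ROI means.

Validation arithmetic follows the bench convention: expected RR from the
certified pair via the RR formula; percentage error
Δ% = 100 (RR_measured − RR_expected)/RR_expected, with an integer-rounded
variant (round half away from zero, which reproduces the published
rounding) for report tables. The repeatability report summarizes rows ×
time points by the overall max |Δ| and the max within-row Δ range — the
latter estimating the error between two RR measurements of the same
subject at different times. The packaged reference table reproduces 22 of
its 24 reported integer Δ cells when recomputed from the unrounded
certified tube values; one 813/500 row is internally inconsistent in the
source sheet (no expected value reproduces all three of its cells under
any rounding), which the test suite documents rather than hides.

## Export

T1 maps are written as DICOM secondary-capture images storing unsigned
16-bit integers with rescale slope 0.1 (0.05 ms quantization, padding
value 65535 for invalid pixels); RR maps store signed 16-bit integers
with slope 0.01 (0.005 % quantization, padding −32768). Both also export
an 8-bit PNG rendering with a perceptually uniform colormap and fixed
display windows (T1: 0–2000 ms, RR: 0–100 %), invalid pixels black.
Every artifact embeds a digest of the run configuration. Flip-angle
series are read/written as standard MR DICOM files grouped by
SeriesInstanceUID and the FlipAngle tag, slices selected by
InstanceNumber.

## Numerical notes and limitations

- The noiseless dual-angle round trip recovers T1/M0 to ~1e-12 relative
  error for angle pairs at least ~1° apart; for nearly coincident angles
  the two-point slope loses precision to float64 cancellation, which is a
  property of the estimator's conditioning, not of the implementation.
- Problem sizes: simulations run on the full 208×256 matrix; the
  acceptance script renders 4 noiseless + 4 B1/noise + 12 repeatability
  acquisitions and 1000 random inversion cases, completing in seconds.
- Only two-angle fitting is provided (multi-angle weighted least squares
  is out of scope), one slice at a time (no volumetric RR), with no
  motion correction and no B1 estimation.
- In vivo cohort statistics (group medians, ICC, nonparametric tests)
  require patient data and are outside the package; the tools stop at
  per-patient RR.
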