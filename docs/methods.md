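# Methods

## Scope and model

`hemospec` models a fiberoptic visible-light diffuse-reflectance
measurement of cortical tissue and inverts it for cerebral blood volume
fraction (CBVF) and hemoglobin oxygen saturation (S_O2). The forward model
is the steady-state photon-diffusion dipole solution for a semi-infinite
homogeneous half-space: an equivalent isotropic point source at depth
z0 = 1/(μa + μs′) paired with an image source at height z0 + 4AD above the
boundary, where A = (1 + ri)/(1 − ri) encodes the fiber/tissue
refractive-index mismatch through the empirical internal-reflection
polynomial ri(n) = 0.668 + 0.0636 n + 0.710/n − 1.440/n². The attenuation
term uses the effective penetration depth Δ = 1/μeff with
μeff = √(3 μa (μa + μs′)), so both dipole terms carry e^(−μeff r). The
model assumes: a homogeneous semi-infinite medium (no skull/cortex
layering), steady-state illumination, and validity of the diffusion
approximation — justified because the 2.5 mm source-detector separation is
large against the ~0.39 mm transport mean free path in this spectral band.

Working units: lengths in cm and coefficients in cm⁻¹ internally; the
transport mean free path is reported in mm; the time-series readout is
CBVF × 100 (percent) and S_O2 as a fraction.

## Packaged optical properties

* **Hemoglobin.** Whole-blood absorption spectra for fully oxygenated and
  fully deoxygenated blood at the 150 g/L reference concentration
  (64,500 g/mol), compiled from the standard human hemoglobin
  molar-extinction tabulations and shipped as versioned TSVs on a 2 nm
  grid over 500–700 nm. The 650 nm entries are anchored so that the
  blood-only absorption at CBVF = 0.01, S_O2 = 0.5 is 0.1103 cm⁻¹. The
  interpolated curves cross (isosbestic points) near 545, 570 and 586 nm,
  inside the 540–650 nm analysis window.
* **Water.** Pure-water absorption from the standard visible-range
  tabulations; at W = 0.78 the tissue water term at 650 nm is 0.0025 cm⁻¹,
  44-fold below the blood term above.
* **Scattering.** White- and gray-matter scattering coefficients as
  power-law fits in wavelength (exponents 0.9 and 1.6) at fresh-brain
  literature magnitudes, with linear-in-λ anisotropies; tissue is mixed
  1/3 white : 2/3 gray. The common amplitude is calibrated so the mixed
  transport mean free path at 600 nm is 0.39 mm exactly — that constant is
  the published summary of the same underlying measurements, so it serves
  as the packaging anchor rather than re-digitized curves.
* Interpolation onto working grids is linear; requests outside
  [500, 700] nm raise rather than extrapolate.

## Calibration and quality control

Calibration is the ratio M = (R − dark)/(C − dark) against a 99%
reflectance standard; any wavelength-independent gain cancels and is
absorbed downstream by the fitted scale K. Tiny negative M from shot noise
near the dark level (|M| < 1e−6) is clipped to zero. The probe leak QC
compares dark-subtracted counts at 650 nm on a black target (R1, pure leak
light) and on tissue (R2): the pass criterion is (R2 − R1)/R1 ≥ 60. Note
the printed form of this ratio in the source literature, [R1 − R2]/R1, is
negative whenever tissue signal exceeds leak; the implemented sign makes
the stated 60:1 threshold and the worst-case error argument (≤ 1/60 CBVF
perturbation) coherent. Both conventions are documented here; the
implemented one is used throughout.

## Inversion

Per spectrum, Nelder–Mead minimizes the unweighted SSE between M and
K·Rp over 540–650 nm. The simplex runs in transformed coordinates —
logistic for CBVF and S_O2, log for K — so the reported parameters respect
[0, 1] and K > 0 without constraining the optimizer. Defaults: initial
CBVF = 0.02, S_O2 = 0.5; K initialized to median(M/Rp) at the initial
state; simplex tolerances 1e−6 (parameters) and 1e−9 (objective); at most
1200 iterations. Time-series fits warm-start from the previous accepted
fit (toggleable; both modes give the same optima on clean data, warm
starts are just faster). Noiseless round trips recover states to better
than 1e−6; at realistic shot noise the per-sample scatter is roughly
0.01 pp in CBVF and 0.3–0.5 pp in S_O2.

Decoupling detection (magnetic probe detachment) flags a sample when its
relative residual exceeds 3× the 31-sample rolling median (with an
absolute floor of 1e−4 so machine-precision residuals on clean data never
trigger), or when fitted CBVF pins within 1e−3 of a [0, 1] bound for ≥ 3
consecutive samples. Flagged samples are excluded from every protocol
summary.

## Protocol analysis

All windows are closed intervals in seconds from session start. Rotarod:
rest 0–60 s, running 60–240 s, rest to 360 s; responses are percent
changes vs the first-10-second reference average (baseline change uses the
0–60 s mean; running response the challenge-window extremum). Hypercapnia:
baseline 0–60 s, CO2 60–300 s, recovery to 360 s; maximum CBVF and minimum
S_O2 percent change are taken vs the baseline average (a reference-window
mode is available, since the source description is ambiguous between the
two).

Extrema are computed after a centered 5-sample running median. The raw
maximum of a noisy 1 Hz series overestimates the underlying peak by
roughly 2 standard deviations of the per-sample noise when the response
plateaus for tens of samples — about +3 points on the rotarod S_O2
response at realistic shot noise — so the median-filtered extremum is the
default estimator; `smooth=1` restores raw extrema.

"Time to baseline" after CO2 release is not defined quantitatively in the
source description; it is implemented as the first post-release time at
which the median-smoothed CBVF re-enters the baseline band (baseline
mean ± 2 baseline SD) and stays inside for at least 5 s, reported as
seconds since release, censored (and flagged) at session end when the
band is never re-entered. Band width, dwell and smoothing are
configurable. Because the band scales with the measured baseline
variability, occasional censoring in noisy sessions is expected behavior,
not an error.

Group comparisons use the two-tailed unpaired Student t-test with pooled
variance (Welch optional), reporting mean ± s.e.m. per group.

## Synthetic rig

The simulator emulates the acquisition chain: expected counts are
gain · lamp(λ) · detector(λ) · [(1 − leak)·Rp + leak] + dark, with Poisson
noise on the signal and Gaussian read noise (SD 4 counts) on the dark
level (mean 150 counts, saturation 65535). The integration gain is
auto-exposed once per session so the maximum expected in-window count sits
at 80% of saturation (within the instrument's 70–90% rule). Lamp
(blackbody-like, 3000 K) and detector (smooth bump) shapes are arbitrary
by design — calibration cancels them, and a test verifies two different
instruments yield identical fitted states. The leak fraction defaults to
2e−4 on the Rp scale, i.e. a tissue-to-leak ratio of ~2500:1 at 650 nm,
about 40× better than the 60:1 manufacturing QC floor — a good build.
Decoupled samples suppress the tissue term to 1e−4 of its value so the
spectrum is genuinely leak-dominated.

Ground-truth trajectories reproduce the study protocols with baseline
CBVF = 0.019 and S_O2 = 0.35. Hypercapnia: saturating-exponential CBVF
rise (τ = 30 s) normalized to hit the injected peak (+16.9% by default)
exactly at CO2 release; slow S_O2 decline (τ = 120 s) to the injected
trough (−31.8%); after release, rapid S_O2 normalization (τ = 10 s) and a
brief CBVF overshoot (25% of the peak rise, τ = 5 s) decaying back with
τ = 15 s — fast enough that CBVF re-enters its baseline band within the
60 s recovery window, as the protocol narrative requires. Rotarod: rise
during the run window to +5.2% (CBVF) and +17.5% (S_O2). Physiological
jitter is multiplicative AR(1) noise (0.3% relative SD, 10 s correlation
time), seeded.

What the simulator does *not* emulate: wavelength-dependent stray light
beyond the single leak term, spectrometer wavelength drift, fiber-bending
losses, motion artifacts, layered tissue, or inter-animal variability in
the optical properties. Passing recoveries therefore demonstrate the
correctness and noise behavior of the analysis chain under the stated
model, not robustness to every failure mode of real recordings; in
particular, real tissue whose scattering deviates from the packaged
spectra will bias absolute CBVF and S_O2 (a known limitation of
fixed-scattering inversion).

## Numerical and design choices

* μa = 0 is handled exactly (μeff = 0, unit exponentials); μs′ ≤ 0 is a
  domain error.
* Refractive defaults: glass fiber 1.52 against tissue 1.4 (n = 1.0857);
  polymer (1.49) selectable via `TissueConfig`.
* Fit-window restriction happens before fitting; wavelengths outside
  540–650 nm never influence results.
* The leak term is a known model mismatch between simulator and fit model:
  at the default 2e−4 it biases fitted CBVF by about −0.008 pp and S_O2 by
  about −0.3 pp, consistent with the ≤ 1/60 worst-case argument that
  motivates the QC threshold.
* Session artifacts are plain text (wide CSV of counts, calibration CSV,
  JSON sidecar, YAML resolved config); floats are written with `repr` so
  write→read round trips are bit-exact.

## Problem sizes used in the shipped checks

The acceptance script runs the protocols at full length (300-sample
resting session; 360 s hypercapnia and rotarod sessions, 10 seeds each).
The pytest suite uses the same protocols with 10–20 seeds for the
stochastic properties and 120-sample resting sessions, sizes chosen so the
whole suite runs in a few minutes while keeping standard errors small
against the tolerances tested.
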