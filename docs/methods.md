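# Methods

## Beam and excitation model

The excitation is a stigmatic Gaussian focus.  Normalised to the focal
intensity, `I(x,y,z) = (w0²/w(z)²)·exp(−2(x²+y²)/w(z)²)·exp(z/lₑ)` with
`w(z) = w0·sqrt(1+(z/(n·zR))²)` and the in-vacuum Rayleigh length
`zR = πw0²/λ`.  `z` is measured from the geometric focus, positive toward
the sample surface; the `exp(z/lₑ)` factor is the ballistic scattering loss
toward the focus.  m-photon fluorescence is generated ∝ `I^m`
(m = 2 or 3; m = 1 is admitted only as a degenerate limit for checks).
Raising the lateral Gaussian to the m-th power narrows the 1/e² radius to
`w0/√m`: for w0 = 0.55 µm this gives 0.39 µm (2P) and 0.32 µm (3P).  The
on-axis axial profile is `(1+(z/(n·zR))²)^(−m)`.

Default parameters: λ = 1.040 µm, w0 = 0.55 µm (the characterised
instrument: an underfilled 1.05-NA objective; an overfilled aperture would
give 0.41·λ/NA ≈ 0.4 µm), n = 1.33 for an aqueous sample.

**Axial scale pinned by focal geometry.**  For the depth-limit
reproduction the axial scale is not taken from an assumed refractive index
but from the measured focal-volume geometry: a focal half-width of 5.8 µm
equal to 3.5 in-medium Rayleigh lengths pins `n·zR = 5.8/3.5 = 1.657` µm
(`BeamParameters.from_focal_geometry`).  With w0 = 0.55 µm this implies an
effective n ≈ 1.81 — not a physical refractive index, but the axial scale
consistent with the stated focal geometry; the two stated numbers (5.8 µm,
3.5 zR) cannot both hold for n = 1.33, and we treat them as jointly
authoritative rather than guessing n.

**Bead convolution.**  PSF measurements use fluorescent beads of finite
size, so the model provides the m-photon excitation density convolved with
a uniform solid sphere.  The sphere is sampled on a grid with step
≤ diameter/25 (radius error < 1% against the analytic limit; verified in
tests against a brute-force 3-D FFT convolution at 10 nm sampling, which
agrees to 0.01%).  Effective 1/e² radii are read off the convolved profiles
by log-linear interpolation.

## Signal, background, and the SBR

At imaging depth d the focal signal integrates `I^m` over |z| ≤ 5.8 µm and
the full lateral plane; the background integrates from 5.8 µm up to the
surface (z = d).  Fluorescence generated above the surface does not exist,
and the region below the focus contributes negligibly (its excitation is
exponentially suppressed).  The lateral integral is closed-form per slab
(`(w0²/w²)^m·πw²/(2m)`), so both quantities are 1-D adaptive quadratures
(`scipy.integrate.quad`).

Attenuation is referenced to the generation depth: each slab carries
`exp(−(d−z)(m/lₑ + 1/Lₐ))`, combining the ballistic excitation loss from
the surface (surface power is the invariant) and emission absorption on
the way out (default Lₐ = 500 µm; excitation absorption is neglected, as
appropriate for 2P/3P excitation below 1400 nm).  This form is identical
to applying an overall `exp(−m·d/lₑ)` prefactor to the focus-normalised
integrals but is overflow-free at any depth and scattering length.  A
consequence used by the tests: `focal_signal(d)/focal_signal(0) =
exp(−m·d/lₑ−d/Lₐ)` exactly.

**Sparsity.**  Fluorescent structures fill only a fraction f of the volume
(default 0.10 for dense mycelium; ~0.01 for labelled cortical neurons)
while the structure in the focus is fully fluorescent, so the focal term
is multiplied by 1/f and the SBR scales inversely with labelling density.
The quoted depth-limit figure is computed from the homogeneous-medium
ratio (f = 1): sparsity is a pure linear rescaling of the ratio and is
kept out of the reference figure, which matches how the simulated maps
focus on the scattering length alone.  With the pinned focal geometry and
the defaults (3P, lₑ = 120 µm, Lₐ = 0.5 mm) the SBR reaches 1:1 at
≈ 811 µm, consistent with the observed ~780 µm imaging depth at maximum
power in a medium-dense sample.

**depth_at_sbr** solves `SBR(d) = target` by bisection to 1 µm inside a
[12, 2000] µm bracket, after checking monotone decrease on a coarse probe
and raising a no-crossing error otherwise (e.g. lossless media).
**sbr_map** accumulates the background integral along the depth grid once
per scattering length (segment quadratures carried forward with the
interval attenuation factor), so a full (depth, lₑ) map costs one
quadrature per cell; iso-ratio contours are exported at
{20, 10, 5, 2, 1, 1/2, 1/5, 1/10, 1/20, 1/50, 1/100}.

Model-structure facts verified in the test suite, with their validity
domains (established numerically):

* 3P SBR ≥ 2P SBR everywhere either ratio exceeds the 1/100 contour floor.
  Beyond ~13 scattering lengths (SBR ~ 1e−7) the ordering flips, because
  the 3P focal signal decays as `exp(−3d/lₑ)` while both backgrounds are
  surface-dominated — an academic regime far below usable contrast.
* With Lₐ = ∞ and f = 1, `SBR·lₑ^(2m−3)` collapses onto a function of
  d/lₑ in the surface-dominated (deep) regime, reflecting the
  `z^(2−2m)` tail of the laterally integrated excitation.  At moderate
  depth the 3P background is instead dominated by the region just above
  the focal volume and is nearly lₑ-independent; the depth limit is
  therefore superlinear in lₑ (also asserted over 60–200 µm).

## Stack analysis

Pixel values are detector counts; histograms use unit-width integer bins.
The per-slice background is the histogram mode (ties to the lowest value —
conservative), valid when structures are sparse enough that most pixels
see no in-focus fluorophore.  The signal is a histogram threshold minus
the mode, with two strategies applied identically to all channels of a
stack: the highest value occurring more often than a pixel-count
threshold, or the highest value with more than a given fraction of pixels
brighter.  If no value satisfies the predicate the slice reports zero
signal and is flagged.  Both levels are shift-equivariant in an additive
offset.

SBR profiles use the top-slice zero convention: the zero value is one
count below the top slice's background, making the top-slice background
exactly 1 count and keeping every ratio finite; deeper backgrounds are
clamped to ≥ 1 count above zero.  Slice i sits at depth i·z_step.

Defaults: `brighter_fraction = 0.002`, chosen so ~10%-fill synthetic
stacks yield top-slice SBR in the 20:1–100:1 range typical of sparse
autofluorescent samples; exposed in configuration because real thresholds
are tuned per measurement.

**Estimator validity.**  When the true SBR drops below ~1, the brightest
0.2% of pixels are background-texture pixels, not in-focus structure, and
the "signal" estimate measures the texture amplitude instead.  The
closed-loop tests therefore compare analysis to model only where the
background is resolved (≥ 5 counts above zero) and the model SBR ≥ 1;
within that domain the blind re-analysis of rendered stacks tracks the
model within a factor of two.

**Fits.**  The excitation nonlinearity is the least-squares slope of
log(signal) vs log(power) (with standard error and residual RMS); the
attenuation length is the inverse slope of ln(surface power) vs depth for
constant focal brightness, with a delta-method standard error, an
infinite-length sentinel for flat schedules, and a warning (not an error)
for non-monotone schedules.  PSF radii are fitted per axis as Gaussians
with a constant-background nuisance term through the brightest connected
spot; the axial profile is not exactly Gaussian, so the axial radius is an
effective 1/e² estimate (~6% below the profile's true 1/e² crossing for a
500 nm bead), while lateral radii agree with the convolved model to ~1%.
Fourier low-pass filtering zeroes radial frequencies above a cutoff;
cutoffs at or above the sampling Nyquist frequency are a no-op, since the
filter exists to remove pixel noise above the optical band limit, never to
alter resolution.  All fits are single least-squares estimates; no
multiple-testing machinery is involved.

## Synthetic data

The generator emulates the study conditions: intertwined filaments
occupying ~10% of the volume, three detection channels (blue = pure 3P,
red = pure 2P, green = mixed 2P+3P), exponential ballistic loss,
depth-dependent out-of-focus background, emission absorption, detector
offset, Poisson photon noise and Gaussian read noise, 16-bit clipping
(flagged).  Every generator is deterministic under a fixed seed; streams
are `default_rng([seed, tag])` with fixed per-purpose tags so outputs are
independent of which others are generated.

* **Scenes** are persistent random-walk tubes (radius 0.5 µm, step 0.5 µm,
  direction persistence 0.9, length 40 µm, per-filament brightness
  lognormal with CV 0.2) grown until the voxelised fill fraction reaches
  the target.  Filament morphology parameters are phantom plumbing, not
  measured statistics.
* **Rendering** applies the lateral m-photon PSF in-plane and an axial
  weighting from the on-axis profile (a full-3D bead-convolution path
  exists for PSF stacks), scales the in-focus term with the model focal
  signal and the background with the model background signal (so the
  rendered stack embodies the model's SBR-vs-depth), and modulates the
  background with a smooth multiplicative texture (Gaussian-filtered
  noise, 10 µm correlation, 20% amplitude) emulating slowly varying sample
  inhomogeneity.  The axial kernel is normalised so that one filament of
  the default radius crossing the focal plane responds with the full model
  focal signal: the model's focal integral spans ±5.8 µm while a 1 µm
  filament spans about half of the excitation-weighted column, and the
  renderer's brightness scale is defined per in-focus filament so that
  blind re-analysis estimates the model ratio without a geometric bias
  factor.  `photon_scale` (default 80 counts per in-focus filament at the
  reference power) sets the top-slice SBR in the 20:1–100:1 regime.
* **Power series** use 10 levels over one decade (geomspace 0.1–1.0,
  matching a power sweep normalised to the highest power), channel
  responses blue `P^3.09`, red `P^1.96`, and green a weighted 2P+3P
  mixture with frozen weights (0.0631·P² + 0.9369·P³) calibrated once so
  the noiseless least-squares log–log slope over the default grid is
  exactly 2.81 (only the net slope is known for the green channel, so the
  split is a documented generator constant).  Noise is lognormal with
  mean 1 and CV 0.05.
* **Power schedules** follow `P0·exp(d/lₑ)` (low-density default
  lₑ = 170 µm, 6 depths over 0–500 µm, 5% noise) with an optional cap
  emulating the maximum available laser power, flagged as truncation.
* **Bead stacks** render a 0.5 µm sphere through the m-photon PSF on a
  0.1 µm / 0.25 µm grid (radial evaluation interpolated onto pixels).

What the phantoms do *not* emulate: photobleaching and photochemistry,
sample motion and drift, spectral overlap between channels, anisotropic
scattering or radiative transport, and real mycelium morphology statistics.
Passing closed-loop tests therefore validates the analysis chain and the
internal consistency of model and renderer — not the biological realism of
any particular stack.

## Problem sizes and numerical choices

Test and verification runs are sized for a desk machine: closed-loop
stacks use a 38.4 µm field of view, 800 µm depth at 20 µm z-steps
(the render's fine grid is 0.4 µm laterally, 0.5 µm axially); recovery
batteries run 20 seeds for scalar fits and 5 seeds for full renders;
Monte-Carlo oracles use 5–10 million samples.  Quadratures are adaptive
with default tolerances; tightening them moves results by < 0.1%.
Degenerate inputs are defined explicitly: background is zero (SBR
infinite) for foci shallower than the focal half-width; structureless
images yield flagged zero signal; flat power schedules yield an infinite
attenuation length; mode ties break low; bisection brackets that contain
no crossing raise a dedicated error.
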