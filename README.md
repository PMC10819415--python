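# mpdeep

Signal-to-background modelling and z-stack analysis for two- and
three-photon (2P/3P) deep imaging of dense autofluorescent samples, such as
*Streptomyces* mycelial communities.

## The problem

Label-free multiphoton imaging of bacterial communities excites endogenous
fluorophores at a single long wavelength (1040 nm): three-photon absorption
reaches the blue/UV fluorophores, two-photon absorption the orange/red ones.
Deep in a scattering sample the ballistic excitation decays as
`exp(-d/le)`, and fluorescence generated *above* the focus (mostly near the
surface) eventually rivals the focal signal.  The imaging depth limit is
therefore set by the signal-to-background ratio (SBR), not by raw signal.
This package implements:

* the Gaussian-beam excitation model and its m-photon point-spread function
  (PSF) geometry, including convolution with finite fluorescent beads;
* a quadrature simulator for focal signal, out-of-focus background, and SBR
  versus depth and scattering length, for m = 2 and m = 3;
* the histogram-based z-stack analysis used on real data: per-slice
  background (histogram mode) and signal (histogram threshold), SBR
  profiles, log–log power-series slopes (excitation nonlinearity),
  attenuation-length estimation, PSF fitting, Fourier low-pass display
  filtering;
* a synthetic-data generator (filamentous phantoms rendered through the
  same optics, with detector offset, Poisson and read noise) so the whole
  pipeline is testable with known ground truth.

## The model

Relative to the focal intensity, a focused beam in a medium with scattering
length *l*ₑ and refractive index *n* is

```
I(x,y,z) = (w0²/w(z)²) · exp(−2(x²+y²)/w(z)²) · exp(z/lₑ)
w(z)     = w0 · sqrt(1 + (z/(n·zR))²),     zR = π·w0²/λ
```

with *z* measured from the focus, positive toward the surface.  m-photon
fluorescence is generated ∝ `I^m`.  The SBR at imaging depth *d* is the
excitation integrated over the focal volume (|z| ≤ 5.8 µm, full lateral
plane) divided by the integral from 5.8 µm up to the surface, each slab
attenuated by `exp(−(d−z)(m/lₑ + 1/Lₐ))` (ballistic loss referenced to the
surface plus emission absorption over length *L*ₐ).  The lateral integral
has the closed form `(w0²/w²)^m · πw²/(2m)` per slab, reducing everything
to fast 1-D quadrature.  Fluorescent structures occupying a fraction *f* of
the volume boost the focal term by 1/f, so the SBR scales inversely with
labelling density.

## Worked example

```python
import mpdeep as mp

beam = mp.BeamParameters()            # 1040 nm, w0 = 0.55 µm
print(mp.psf_lateral_radius(beam, 3)) # 0.3175...  µm (3P PSF, 1/e²)
print(mp.psf_lateral_radius(beam, 2)) # 0.3889...  µm (2P PSF)

# depth at which 3P SBR falls to 1:1 for a 120 µm scattering length,
# using the measured focal geometry (half-width 5.8 µm = 3.5 axial units)
print(mp.reference_depth_limit(scattering_length_um=120.0))  # 810.9 µm
```

The same numbers from the shell, plus the synthetic recovery loops:

```
$ mpdeep simulate-sbr --order 3 --le-um 120 --fill 1.0 \
      --refractive-index 1.813 --depth-max-um 900 --target-ratio 1 -o curve.csv
depth at SBR 1: 811 µm

$ mpdeep synth-power --seed 7 -o powerdir
blue: power-law fit: S ∝ P^3.089 (SE 0.016, residual RMS 0.032, n=10)
green: power-law fit: S ∝ P^2.811 (SE 0.030, residual RMS 0.062, n=10)
red: power-law fit: S ∝ P^1.960 (SE 0.018, residual RMS 0.037, n=10)
```

The blue channel is purely three-photon excited (slope ≈ 3), the red
channel two-photon (slope ≈ 2), and the green channel a 2P+3P mixture
(slope ≈ 2.8).  `curve.csv` holds depth, focal signal, background and their
ratio; `simulate-sbr --map-le-range 40 300` adds the (depth, scattering
length) contour map.  `mpdeep synth-stack | analyze-stack` renders and then
blindly re-analyses a filamentous phantom; `synth-beads | psf-fit` does the
same for bead-based PSF measurements.

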