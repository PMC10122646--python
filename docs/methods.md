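# Methods

## Forward model

A spectrum is sampled on a uniform wavenumber grid k = 2π/λ spanning the
wavelength window [λ₀ − Δλ/2, λ₀ + Δλ/2] (defaults λ₀ = 840 nm,
Δλ = 160 nm, 1024 samples). For an object with interfaces at cumulative
single-pass optical distances z_j, amplitude reflectivities r_j and
accumulated dispersion D_j = β_front·L_front + Σ_{m≤j} β₂,m·L_m, the
noiseless spectrum is

    S(k) = G(k) · | 1 + Σ_j r_j exp(i·2·(k·z_j + ½·D_j·Ω²)) |²,
    Ω = c·(k − k₀),

with a unit-peak Gaussian envelope G centred at k₀ = 2π/λ₀. The factor 2
is the double pass of the reflective geometry. Only the second-order
(group-velocity) dispersion phase is modelled: higher even orders and odd
orders are omitted because β₂ is the quantity the method extracts; their
effect on peak shapes would be second-order at the bandwidths involved.
The modulus squared automatically generates the inter-interface
autocorrelation (artefact) fringes at distances z_j − z_l.

Units: optical distances in µm, wavenumbers in rad/µm, GVD in fs²/mm;
Ω in rad/fs with c = 0.299792458 µm/fs, so D·Ω² (after the fs²/mm·µm →
10⁻³ fs² conversion) is in radians.

**Envelope width.** The envelope σ_k is set per grid so that the
simulated axial point-spread FWHM (magnitude A-scan of a single
reflector) equals the configured axial resolution, 4.08 µm by default.
The unbounded-Gaussian closed form σ_k = √(2 ln 2)/FWHM_z underestimates
the width of the realised point spread by ~7 % because the 160 nm window
truncates the Gaussian at ±2.5 σ, so σ_k is solved numerically against
the windowed transform (Brent's method; cached per grid). With a 160 nm
window the point-spread floor is ≈ 2.7 µm; requesting a finer resolution
raises an error.

**Noise.** Additive i.i.d. Gaussian noise on the spectrum with
σ = A_ref·10^(−SNR/20), where A_ref = 2 is the peak fringe amplitude of a
maximum-modulation (r = 1) single-interface spectrum on the unit-peak
envelope. The reference is object-independent, so one SNR dial produces
the same absolute noise level for every object; supported levels for
training studies are 45/35/30/25 dB plus noiseless.

**Random objects.** All object parameters are drawn uniformly:
interface count 1–5, layer optical thickness 20–300 µm, β₂ in
(−5000, 5000) fs²/mm, amplitude reflectivity 0.1–1.0, front distance
50–400 µm. Draws that exceed the unambiguous depth π/(2δk) ≈ 1117 µm are
rejected and redrawn. Dataset streams derive one child random stream per
item from the base seed (SeedSequence spawning), so they are reproducible
and lazily generated.

## The Qm-OCT transform

`fft_stack` implements: analytic signal of the mean-subtracted spectrum
(Hilbert transform; applied once to the full 1024-sample spectrum, since
a 20-sample fragment is too short for a stable Hilbert pair) → split into
50 contiguous fragments of ⌊1024/50⌋ = 20 samples (the trailing 24
samples are discarded) → full linear autocorrelation of each fragment
(39 lags, zero lag centred) → symmetric zero-padding to 2048 → FFT →
magnitude of the first 1024 bins. Rows are fragments, columns depth.

**Background suppression.** After mean subtraction the source envelope
survives as a slowly varying background; per fragment it autocorrelates
into a broad zero-distance lobe (~50 columns for 20-sample fragments)
that buries shallow depth bins and shifts artefact-peak apexes by several
pixels through interference. `fft_stack` therefore high-passes the
analytic signal in the depth domain (zeroing structure shallower than
40 µm optical distance, raised-cosine edge) before fragmentation. With
it, all significant fragments of a single-reflector stack peak in the
same column; structure shallower than the cutoff is declared out of range
(the object generator's minimum front distance is above it). The step is
parameterised (`background_cutoff_um`, `None` disables).

**Depth calibration.** Spectral fringes oscillate at twice the
single-pass optical distance, so the stack column pitch is half the
Fourier-conjugate pitch of the padded transform:
pitch = ½·2π/(2048·δk) = 1.0914 µm/px on the default grid. Pixel 200 then
sits at 218 µm and pixel spans 200→280 and 320→600 at 87 µm and 306 µm —
the calibration is cross-checked in the tests by simulating reflectors.
The standard A-scan uses the same single-pass convention,
pitch = π/(pad·δk), verified by the linearity of peak pixel versus
reflector depth (R² > 0.999).

**Artefact signature.** For a dispersionless object, fragment peaks are
column-constant. A layer with accumulated β₂·L makes its back-surface
(and artefact) peaks drift essentially linearly across fragments — about
±3.4 px/row at β₂·L = 5000 fs²/mm × 300 µm on the default grid — with the
drift sign equal to the GVD sign. This drift is the feature the regressor
reads.

## Dispersion profiles and the area algebra

Ground-truth profiles are piecewise constant in the encoded [0, 1] space:
encode(β_front) from pixel 0 to the first interface pixel, encode(β₂) of
each layer over its half-open pixel span [p_j, p_{j+1}), encode(0) = 0.5
behind the last interface. Interface pixels are the depth-axis-rounded
positions; a layer thinner than one pixel contributes no pixels of its
own (the deeper layer's value takes the shared pixel). Encoding clips to
[0, 1]; decoding of out-of-range inputs is an error.

For a two-interface object the parasitic autocorrelation peak splits a
predicted profile into four areas; the apparent GVD between the first
interface and the autocorrelation peak mixes the front and object GVD as
β_area2 = (L_f·β_f − L_o·β_o)/(L_f − L_o), singular at L_f = L_o. The
exact inverse recovers the object GVD from predicted maps. Map statistics
(per-pixel mean/STD, minimum-STD profile selection within a pixel window,
ties to the lowest row) are computed in encoded space and decoded on
request, avoiding clipping asymmetry.

## Regression network

The default architecture mirrors the full-scale design: five blocks of
(convolution → batch normalisation → ReLU) stages with VGG-16 filter
progression 64/128/256/512/512, average pooling, and a residual
combination per block; head = fully connected layer (14336 units) →
dropout 0.1 → layer normalisation → dense output of 1024 units → sigmoid.
The 50 spectral fragments enter as input channels and convolutions run
along the depth axis. The residual "alpha gate" is implemented as a
learnable scalar per block, initialised at 0.5, forming the convex
combination α·pool(conv path) + (1−α)·pool(projected input); the
projection is a 1×1 convolution when the channel count changes. This gate
reading is an interpretation of an under-documented design element and is
config-exposed.

The implementation is plain numpy with hand-written backward passes
(gradient-checked against central finite differences in the tests) and an
Adam optimizer; float32 parameters. Loss is mean absolute error; training
follows the on-the-fly scheme in which object parameters are fixed but
spectra and noise are regenerated every epoch. Reference optimisation
settings: batch 16, Adam, learning rate 1e-4 — appropriate for
full-scale runs (hundreds of thousands of objects, ≥100 epochs, GPU).

**Desk scale.** The bundled smoke configuration uses two blocks (8/16
filters, kernel 5), 64 FC units, and learning rate 3e-3: at 200 objects ×
10 epochs (≈130 optimizer steps) the full-scale rate moves the loss
imperceptibly, so the short run uses a proportionally larger step. The
smoke study conditions are 200 training / 50 held-out two-interface
objects with one thick (220–300 µm) layer of |β₂| ∈ [3000, 5000] fs²/mm
with random sign, front distance 150–250 µm, 30 dB SNR — the
high-contrast regime in which dispersion artefacts are strongest, chosen
because prediction quality grows with within-object GVD contrast. On this
run the encoded-profile MAE drops from ≈0.27 to ≈0.06 in ten epochs and
held-out sign recovery on strongly dispersive pixels exceeds 99 %.

## Reduced-scale studies

* **Variability grid**: per GVD triple, 138 three-equal-layer objects
  with thickness sweeping 4→306 µm; ground truth via profile encoding,
  predictions via the model; summary is mean absolute decoded-GVD error
  per triple.
* **SNR matrix**: one small model trained per noise level, each evaluated
  on matched test sets at every level.
* **Resolution sweep**: one fixed three-interface object (layers −1500
  and +1000 fs²/mm) rendered at axial resolutions 2.72–8.16 µm through a
  single model; reports mean decoded GVD per layer interior.

All three run in minutes on one CPU with the smoke model standing in for
a full-scale network; their outputs are trend indicators and carry their
configuration, not quantitative reproductions of full-scale results.

## What the synthetic data does and does not emulate

The generator reproduces the geometry and statistics of the training
regime (Gaussian envelope, uniform object parameters, additive Gaussian
spectral noise at calibrated SNR). It does not model speckle, detector
fall-off, polarisation, wavelength-dependent reflectivities, shot noise,
or spectrometer nonlinearity beyond what `resample_to_k` corrects.
Passing tests therefore demonstrate the correctness and internal
consistency of the algorithmic chain and the learnability of the
dispersion signature under these idealised conditions — not performance
on real spectrometer data, where envelope shape, SNR structure and
resolution mismatch differ.

## Numerical choices and degenerate inputs

* Autocorrelations are centred before zero-padding, preserving the
  zero-lag phase reference; FFT magnitudes are orientation-invariant to
  this choice.
* Fragments are not windowed before autocorrelation.
* Fragment peak readout (`peak_pixels`) can exclude the shallow-depth
  region and fragments whose peak energy is a small fraction of the
  strongest row; at the band edges the envelope vanishes and those rows
  carry no usable signal.
* `resample_to_k` requires a strictly increasing wavelength axis and uses
  a cubic spline onto a uniform k grid spanning the same interval with
  the sample count preserved.
* Degenerate geometry raises typed errors: objects deeper than the
  unambiguous range (depth overflow), L_f = L_o in the area algebra
  (singularity), generator ranges incompatible with the depth invariant
  (configuration error after bounded retries).
* Sub-pixel layers occupy no pixels of their own in ground-truth
  profiles; vacuum is the exact dispersionless reference (β₂ ≡ 0).
* Water's bundled Sellmeier fit yields ≈21 fs²/mm at 840 nm; literature
  water values near 26 fs²/mm are quoted without a wavelength, so the
  water anchor is treated as qualitative.

## Known limitations

* The regression harness is CPU-oriented; the default full-scale
  configuration (~10⁸ parameters) is constructible but not practical to
  train here, and no attempt is made to reproduce full-scale experimental
  predictions for real glasses or biological tissue.
* Thin, weakly dispersive layers produce artefact changes below the
  detectable scale — the fundamental limitation of dispersion-from-
  broadening approaches — and are likewise out of reach of the smoke
  model.
* The exact supplement-level hyperparameters of the original network
  (kernel sizes, alpha-gate mechanics) are not public; the defaults here
  are canonical VGG-16 choices, all config-exposed.
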