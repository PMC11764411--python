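# Methods

This note documents the models behind `spectraplex`, the parameters that
matter, the numerical choices, and what the simulator does and does not
emulate.

## Forward model

A specimen is modeled as a set of per-pixel, per-stain abundance maps
`a_i(x) ≥ 0`, dimensionless, with 1.0 defined as **calibration-level
deposition** — the staining density of a single-stain reference slide.
Abundances are capped at 3 (an optical density of ~3 per stain is
effectively opaque, and heavier staining promotes non-specific dye
adsorption, so realistic assays stay below this).

Each illumination channel *k* has a band transmission profile `L_k(λ)`
(Gaussian with the channel's center/FWHM by default; top-hat available, and
used for the broadband 420–690 nm white-light channel).  Each camera plane
*p* ∈ {R, G, B} has responsivity `S_p(λ)`.  The rendered specimen intensity
is the white-balanced, band-averaged Beer–Lambert transmission

```
I_p(x) = wb_p · Σ_λ L_k(λ) S_p(λ) 10^(−Σ_i a_i(x) ε_i(λ))  /  Σ_λ L_k(λ) S_p(λ)
```

with `ε_i(λ)` the amplitude-normalized absorbance spectrum of stain *i*;
the blank flat-field is the same expression at zero abundance.  Because the
formula normalizes per plane, a blank field is neutral by construction; the
white-balance gains are the constant 0.9 (blank at 90% of full scale).
Wavelengths run over a 350–950 nm grid at 1 nm, covering the UV (375 nm)
through NIR (880 nm) chromogen bands; integration is restricted to each
band's support and chunked in λ to bound memory.

A consequence of band averaging worth knowing: the band-integrated OD is
exactly linear in abundance only for a monochromatic band.  For the real
28–49 nm bands the deviation is below ~0.01 OD at abundances ≤ 1.5, which
is what limits noiseless round-trip recovery (mean absolute error a few
10⁻⁴, not machine precision).

## Synthetic spectra and camera (stand-ins)

The dye spectra and sensor curves are **parametric synthetic stand-ins**;
no tabulated curves for the deposited dyes or the sensor are available to
this package.  They are shaped to reproduce the qualitative couplings that
drive the method:

* chromogen peaks sit at their channel centers (AMC 375, NMC 405, sCy7 769,
  ir870 880 nm) with FWHMs of 59–106 nm, so the two coumarins overlap
  each other and ir870 tails into the 769 nm band (the dominant NIR
  bleed-through);
* hematoxylin is a broad 599 nm band plus a small UV shoulder (12% of peak
  near 370 nm) — the source of hematoxylin-into-UV bleed; eosin peaks at
  520 nm; DAB is a very broad visible absorber, strong at 405 nm (which is
  why a 405 nm channel isolates DAB from hematoxylin and sCy7) and decaying
  into the NIR;
* invisible chromogens are validated to absorb < 10% of peak across the
  460–680 nm visible core (their Gaussian tails necessarily exceed that
  within ~40 nm of the band edges, hence the margins);
* camera planes are visible Gaussians (blue ~460, green ~532, red ~605 nm)
  plus NIR tails arranged so the red plane dominates near 769 nm, the blue
  plane dominates at 880 nm, and **all** planes respond at 880 nm once the
  IR-blocking filter is removed; with the filter in place, response above
  700 nm is zero and every NIR channel raises a degenerate-channel error.

Display colors for the visible dyes are not hand-picked: they are the
band-averaged transmittance of each dye at unit abundance under the
white-light channel, computed from these same spectra.  This makes the
reconstructed H&E composite consistent with the simulated white-light
capture by construction (mean per-plane error ~0.005 in transmittance
space).  Chromogen pseudo-colors are legibility choices and user-overridable.

## Assay configurations

Six assay configurations mirror the demonstrated specimen classes
(melanoma 1-plex, breast HER2 1-plex, Hodgkin 2-plex, breast 3-plex,
DAB + sCy7 duplex, prostate 4-plex).  Every assay carries the white-light
H&E channel, which is display-only and never unmixed.  Multiplex assays add
narrowband visible channels for eosin and hematoxylin so the counterstains
can be unmixed alongside the chromogens; the prostate H&E + 4-plex assay
thus supplies six unmixing channels (375/28, 405/30, 769/49, 880/40, eosin,
hematoxylin).  The eosin channel wavelength is assay-specific (520 nm for
the breast triplex, 530 nm for prostate), reflecting that the choice is a
free parameter near the eosin peak rather than a physical constant.
Configuration build validates identifiability: each unmixed stain must
dominate at least one channel, the effective-absorbance matrix must have a
column-normalized condition number < 10³, and stain count must not exceed
channel count.

Per-channel matched planes are chosen automatically: argmax over planes of
effective absorbance weighted by in-band responsivity (ties break
red > green > blue).  This yields blue for the UV and 880 nm channels, red
for 769 nm and the 599 nm hematoxylin channel, green for eosin.

## Virtual tissue

Cells are non-overlapping ellipses placed by rejection sampling: an
elliptical nucleus (semi-axes 3.5–5.5 px), a concentric cytoplasm
(1.6–2× larger), and a 2-pixel membrane ring just outside the nucleus.
Every cell receives hematoxylin in its nucleus (abundance 0.6–1.2) and, when
eosin is in the assay, eosin in its cytoplasm (0.3–0.8).  Phenotypes are
assigned per cell by frequency; each phenotype deposits its markers into
their declared compartments at abundance 0.5–1.5 by default — i.e. around
calibration level, as assays are tuned to be.  Co-expression (e.g.
CD30+CD15 on the same membranes, HER2+ER+PR in one cell) is expressed as a
single phenotype with multiple markers.  Default cell density is one cell
per 800 px²; the generator raises an error when the requested count cannot
be packed.  Regeneration with the same seed is bit-identical.

What the simulator does **not** emulate: tissue texture (stroma, necrosis),
staining chemistry and protocol-order effects, chromatic aberration or
registration error between channels (a single fixed camera is assumed, so
channel registration is perfect by construction), Bayer demosaicing (images
are full-resolution three-plane), absolute radiometry (exposure is a pure
multiplier applied to capture and blank alike), and fluorescence emission
(chromogens are pure absorbers).  Passing round-trip tests therefore
demonstrates correctness of the spectral pipeline, not robustness to
real-slide morphology, registration or chemistry variation.

Noise is the standard CMOS model: Poisson shot noise on a photon scale
(`shot_noise_scale` = photons at full-scale intensity; 10⁴ in the noisy
round-trip checks) plus Gaussian read noise, applied per plane after band
integration.  The blank is treated as a noiseless (time-averaged)
flat-field.  Noise streams are seeded per channel so runs reproduce exactly.

## Calibration

Optical density is `OD = −log10(max(I, floor)/I₀)` clipped to [0, 4], with
`floor = 10⁻⁴` of full scale; the floor/cap prevent infinities from dark
pixels, and 4 OD exceeds any simulated signal.  Negative OD (specimen
brighter than blank) clips to zero.

Reference coefficients are measured from simulated single-dye,
uncounterstained slides rendered under the identical channel set: the
stained-pixel mask is an Otsu threshold on the stain's own channel OD
(reproducible without manual ROIs), and the per-channel **median** OD over
the mask forms the stain's column (median rather than mean for robustness
to partial-coverage edge pixels).  The default normalization keeps the raw
OD-per-unit-abundance column (`matched_channel_unit`): abundances then read
directly as fractions of calibration-level staining, a perfectly recovered
calibration slide unmixes to exactly 1, and the own-channel entry is the
column maximum.  Rescaling the column to 1 in its own channel was rejected
because it folds each stain's own-channel OD into the abundance scale and
biases recovery by ~17% for the NIR dyes.  An `unit_l2` scheme is available
when only relative signatures matter.  On noiseless simulator data the
calibrated matrix agrees with direct band integration of the forward model
to ~10⁻⁸ per entry; assembly warns (without failing) when the
column-normalized condition number exceeds 10³.

## Unmixing

Per pixel, `a = argmin_{a≥0} ‖M a − b‖₂` (non-negative least squares —
abundances are physical stain quantities, so clipping an unconstrained
solution was rejected).  No spatial regularization is applied; per-pixel
independence keeps the solver exactly equivalent to its per-pixel oracle
and invariant to visitation order.  The vectorized implementation solves
the unconstrained least squares for all pixels at once (identical to NNLS
wherever already non-negative), iteratively drops negative supports with
pixels grouped by support pattern, verifies the NNLS KKT conditions, and
re-solves the rare violators with SciPy's reference solver; tests confirm
agreement with the per-pixel solver to 10⁻¹⁵ and with exhaustive grid
search on two-stain toys.  Overdetermined stacks are solved in the
least-squares sense; underdetermined configurations are rejected at config
build.  The residual image reports the per-pixel RMS of `M a − b`.

## Composites

Brightfield composites multiply per-plane transmittances,
`T_p = Π_i c_ip^{a_i}` on white — chosen over full spectral re-rendering so
the algebra is exact (multiplicativity over abundance partitions holds to
machine precision) and testable.  Fluorescence-like composites add
`a_i · fluor_color_i` on black and clip.  The DAB-mimic view is a
brightfield composite with fixed brown/blue transmittance triples; H&E
reconstruction applies optional per-dye gains before compositing.
Saturation adjustment (used at 0.6 for print legibility of deep-blue
UV/NIR captures) scales HSV saturation, preserving hue and value exactly.
Quantitative outputs are 32-bit float TIFF; composites are 8-bit PNG with
no tone mapping.

## Problem sizes

Defaults were chosen so every check runs in seconds on one CPU: round-trip
recovery on 256 × 256 fields (~80 cells, ~65 k pixels per channel, 7
channels), calibration slides at 96 × 96, crosstalk checks on a 40 × 40 px
uniform deposit, and 1000 pixels for the grid-search oracle comparison.
Accuracy conclusions are insensitive to field size since the model is
per-pixel.
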