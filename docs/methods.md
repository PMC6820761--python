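# Methods

This note documents the generative model behind `ftirsim`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot stand in for.

## Spectral model

Absorption bands are Voigt profiles (Gaussian ⊛ Lorentzian), the standard
line shape for condensed-phase mid-IR bands. The "half Gaussian / half
Lorentzian" character is realised as *equal component FWHMs*: for a total
band width `f`, both components get `f_c = f / 1.63760`, where 1.63760 is
the equal-width case of the Olivero–Longbothum FWHM approximation
`f_V ≈ 0.5346 f_L + sqrt(0.2166 f_L² + f_G²)`. Evaluation goes through the
Faddeeva function (`scipy.special.voigt_profile`), which is accurate to
machine precision; the test suite checks it against direct numerical
convolution to 1e-6 relative and verifies area conservation to 1%.

The 16-band table (packaged as `data/band_table.csv`, user-replaceable)
fixes nominal position, width, per-class area, and the randomization SDs:
per-pixel Gaussian jitter of position (0.2–1.8% of the centre), width (1%),
and area (5% globally). The CO₂ band (2352 cm⁻¹) never has its width
randomized. Widths and areas are clipped below at 1e-6 of nominal so a
Gaussian draw cannot go non-positive; the Gaussian choice itself is a
modelling decision — only the SD levels are prescribed by the table.

**Area units.** Band areas are interpreted per *spectral point*: each band
is scaled by the axis step (4 cm⁻¹ by default) on top of its unit-area
normalisation. This reproduces the absorbance scale of pipelines that
convert band positions and widths from wavenumbers into point indices
before evaluating, and it is the only reading consistent with the rest of
the design: with the ×10 absorbance scaling it puts a pure-protein amide I
peak near 0.7 (cube maximum ≈ 1 before any rescaling), which the 0.15
tissue-mask threshold presupposes. Interpreting the areas as integrals
over cm⁻¹ directly (`area_units="wavenumber"`, selectable) yields peaks
~4× lower, a cube maximum sitting on the high-wavenumber baseline instead
of amide I, and a mask threshold that would classify most tissue as
background.

The default axis descends 3856 → 800 cm⁻¹ in 4 cm⁻¹ steps — exactly 765
points. The nominal range is only "around 3850–900", so the 765-point
count is treated as the authoritative constraint and the endpoints as
configurable.

## Spatial phantom

The real class-membership maps come from fuzzy c-means clustering of a
measured pancreatic core; this package substitutes a parametric phantom so
the ground truth is exact and nothing needs downloading. Three smooth
Gaussian random fields (periodic-boundary smoothing, re-standardised,
scaled by a contrast gain of 3) pass through a softmax, giving per-pixel
memberships that sum to exactly 1 inside a circular core and are 0 outside.
The contrast gain saturates memberships towards 0/1, mimicking the
mostly-committed memberships fuzzy clustering produces on structured
tissue. The lipid field uses half the correlation length (4 px vs 8 px at
desk scale) and a −1 logit offset, making it sparser and finer-grained than
the two spatially similar DNA/RNA and protein classes, as is typical of
tissue. The marginal distribution and spatial covariance of real FCM
memberships are not characterised anywhere authoritative; these field
parameters are free knobs, chosen once.

The CO₂ amplitude map is i.i.d. Uniform(0, 1) over the *whole* frame —
atmospheric CO₂ is sample-independent, so background pixels receive the
band too (switch: `co2_on_background`).

Desk scale is 128 × 128 px with a 56 px core radius (≈ 50 MB float32
cube); the 1180 × 1100 px full-scale frame of the reference datasets is an
explicit preset (`SimulationConfig.full_scale()`, several GB per cube).

## Baseline

Scattering artifacts grow roughly linearly with wavenumber for
non-spherical scatterers, so each pixel receives a straight line on the
axis position normalised to [0, 1] from the lowest to the highest
wavenumber: slope ~ U(0.15, 0.25), intercept ~ U(−0.00026, 0), redrawn
independently per pixel, divided by 15 on background pixels (no sample, far
less scattering). The abscissa convention (normalised position rather than
raw wavenumber or point index) is the only one under which a slope of ~0.2
is a physically sensible absorbance tilt; it is recorded here as this
package's convention.

## Optics

The diffraction-limited Airy disc of radius r = λ/(2·NA) is approximated by
an isotropic Gaussian with σ = 0.341·r. (0.341 is the printed constant of
the source design; "r covered by three standard deviations" would give
0.333 — the printed value is used.) Each spectral plane is convolved with
its own σ in pixels, `0.341·(10⁴/ν̃)/(2·NA)/pitch`: 1.86 px at amide I for
the defaults NA = 0.5, pitch = 1.1 µm. Boundary handling is symmetric
reflection with the kernel truncated at 4 SD; symmetric extension with a
symmetric kernel preserves each plane's sum and mean (verified to 1e-6
relative in the tests) and avoids dark rims at the frame edge. Blur is
applied after baseline insertion, matching the stage order of the original
workflow; true Airy (Bessel) convolution and detector MTF are out of scope.

## Noise model and calibration

FT-IR noise is partly multiplicative: the injected Gaussian field has
per-point SD linear in the clean absorbance,

    sd(A) = σ_G · (1 + 0.4 · (A − MIN) / (MAX − MIN)),

so sd(MIN) = σ_G and sd(MAX) = 1.4·σ_G, with MIN/MAX the global extremes of
the clean cube. (The historically printed slope/intercept equations for
this scaling are algebraically inconsistent with the 40% constraint they
were meant to encode; the constraint itself is implemented.)

Noise is *measured* exactly as on real spectra: least-squares line fit on
the band-free 2150–2075 cm⁻¹ window (19 points at 4 cm⁻¹), absolute
residuals, sample SD (N−1), SNR = 1/noise with unit signal; the mean over
tissue pixels summarises a cube. Two properties of this estimator are worth
knowing. First, the 2-parameter fit absorbs part of the noise, so on pure
line + N(0, σ) spectra its expectation is ≈ 0.925·σ·√(1−2/π) ≈ 0.557·σ,
about 7.5% below the naive half-normal SD — harmless in practice because
calibration, targets and reported SNRs all use the same metric. Second, at
a few hundred tissue pixels a single mean-SNR measurement carries ~1%
sampling error; calibration accuracy statements therefore refer to the
desk-scale (≈10⁴ tissue pixel) frame.

Calibration is bisection on log σ_G over [1e-6, 10] against the measured
mean SNR, using one fixed probe noise field drawn once per calibration so
the search is deterministic (whether the original iterative matching
re-drew noise per iteration is unknown; a fixed probe is this package's
choice). Only the estimation window is perturbed during the search — the
metric sees nothing else — making each iteration cheap. Convergence is
|SNR − target| ≤ tol_rel·target (default 1%) within 50 iterations; the
best iterate is returned with a warning otherwise.

The scan ladder applies SNR ∝ √N: each of the default
2, 4, …, 256-scan levels is calibrated to `snr_ref·√(N/scans_ref)` and
injected from the same clean parent. `snr_ref = 1000 at 256 scans` is a
placeholder anchor of realistic magnitude — the experimental anchor values
are not published as printed numbers — and should be set from the user's
own instrument when absolute noise levels matter.

Noise is added to background pixels as well; real tiles are noisy
everywhere.

## Signal Distortion metric

Per point, `noise_abs = |noisy − clean|`, `noise_absred = |denoised −
noisy|`, `SD = |noise_absred − noise_abs|`, summed over points where
`noise_absred > noise_abs` *strictly* — equality excludes the point, so
both the identity denoiser and a perfect reconstruction score exactly 0.
The raw sum is reported (as originally defined) together with a per-point
mean for cross-size comparability; summation runs over the full cube (no
spectral sub-range restriction). The metric is pixel-permutation invariant
and scales linearly with a common rescaling of all three cubes.

### Measuring the 40% excess

`noise_excess_at_extremes` estimates the endpoint ratio of the injected
noise empirically: since sd is linear in A, `E|noisy − clean| =
√(2/π)·sd(A)` is linear in A too, so an OLS fit of |noisy − clean| against
clean absorbance, evaluated at the cube's global extremes, recovers
`100·(sd(MAX)/sd(MIN) − 1)` ≈ 40 with sub-percent error at desk scale.
Comparing the SD of residuals over the top vs bottom 1% absorbance
*quantile sets* instead systematically underestimates the excess (≈ 28% at
desk scale): the upper percentile of a tissue cube spans roughly the top
third of the absorbance range, not the neighbourhood of the maximum, while
a "top 1% of the range" slice contains too few points (~20) for a stable
SD. The regression estimator is used by `scripts/acceptance.py`.

## Determinism and problem sizes

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning with fixed per-stage keys, so every
artifact regenerates bit-exactly from its manifest. Band parameters are
drawn in (class, band)-major pixel batches rather than pixel-by-pixel —
distributionally identical, deterministic, and ~30× faster; the
single-spectrum `generate_profile` path consumes its generator in
band-major order and therefore produces a different (equally valid) stream.

Default problem sizes were chosen so a full pipeline run (clean cube plus
the 8-level scan ladder at 128 × 128 × 765) completes in ~2 minutes and
the test suite in ~2 minutes on one CPU core; statistical tolerances in the
tests are set at 3–4 SD of each estimator's sampling distribution at those
sizes.

## What the phantom does not capture

- Real FCM membership maps have anatomically structured, non-stationary
  covariance; the phantom's fields are stationary and isotropic.
- Only three base profiles plus CO₂: real tissue variability (millions of
  molecular species, Mie-type scattering on cellular structures, water
  vapour lines, detector drift) is not represented.
- Baselines are straight lines; resonant-Mie and sinusoidal fringe
  artifacts are out of scope.
- Noise is Gaussian and spectrally white; interferogram-domain effects
  (apodization correlation, detector nonlinearity) are not modelled.

Passing tests therefore demonstrate correctness of the generative model
and metrics as designed, not that any denoiser ranking obtained on the
phantom transfers unchanged to measured tissue data.
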