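# Methods

## Image-formation model and assumptions

All computations assume the linear, shift-invariant, two-dimensional
widefield model: a raw frame is the fluorophore density multiplied by the
excitation field and convolved with the detection PSF,
`D_j = (O · I_j) ∗ H`. The PSF is an isotropic Gaussian parameterized by
its FWHM (`σ = FWHM / (2√(2 ln 2))`), peak-normalized; no Airy rings,
vectorial high-NA effects, aberrations or axial structure are modeled.
The excitation is a perfect sinusoid
`I_j(r) = I0 [1 + m cos(2π k0·r + φ0 − ψ_j)]` with exactly known
parameters; blind estimation of pattern parameters from data is out of
scope, so reconstruction always reads them from stack metadata. Convolution
is evaluated by FFT with periodic boundaries; the scene generators keep all
content at least 3 PSF-FWHM away from the raster border so wrap-around
never reaches the analysis region.

## Spatial-domain reconstruction

For three equidistant phase steps `ψ_j = {0, −2π/3, +2π/3}` the
coefficient fields

    c_j(r) = 1/(3 I0) [1 + (2/m) cos(2π k0·r + φ0 − ψ_j)]

satisfy, identically in both arguments,

    Σ_j c_j(x) I(x' − δ_j) = 1 + cos(2π k0·(x − x')),

so the pixel-wise superposition `Σ_j c_j D_j` equals `O ∗ P` with the
compressed effective PSF `P(r) = [1 + cos(2π k0·r)] H(r)`. Two remarks on
this formula:

* **Modulation factor 2/m, not 2m.** The two readings coincide at `m = 1`,
  but only `2/m` satisfies the identity above for general `m`: the cross
  term `(2/m)·(m/2)·2 cos(a) cos(b)` must carry unit weight for the
  phase-sum to telescope into the pure difference cosine. The test suite
  enforces this with a brute-force oracle over random `(m, T, φ0)`
  configurations (worst error ~1e-14); a `2m` implementation fails it for
  any `m ≠ 1`.
* **Orientations combine by plain summation.** The three per-orientation
  superpositions are summed before a single Wiener deconvolution with the
  summed effective PSF `Σ_d [1 + cos(2π k_d·r)] H(r)`. By linearity this
  is equivalent to deconvolving a single image formed through the combined
  PSF; deconvolving per orientation and summing afterwards would weight
  the bands differently and is deliberately not offered.

The coefficient fields depend only on the grid and pattern and are cached
per `(grid, pattern)` pair, so repeated reconstructions (time series) pay
only the multiply-accumulate and one FFT pair for the deconvolution. The
superposition itself provably invokes no Fourier transform (a test runs it
with `numpy.fft` disabled).

Wiener deconvolution uses `conj(OTF) / (|OTF|² + w²)` with the OTF
normalized to unit zero-frequency value, so `w` is dimensionless on the
same scale regardless of PSF or image normalization. The default
`w = 0.05` is a conventional mid-range value for noise-free to
moderate-noise synthetic data; it is a tuning knob, not a fitted constant.
Negative pixels after deconvolution are clipped to zero for display and
metrology; the unclipped image is retained in the result's provenance.

## Frequency-domain reference

The comparator pipeline is the standard linear-SIM frequency-domain
workflow: per orientation, the three frame spectra are unmixed by
inverting the 3×3 system whose rows are
`I0 [1, (m/2) e^{+i(φ0−ψ_j)}, (m/2) e^{−i(φ0−ψ_j)}]`, yielding the 0 and
±1 order object bands. The matrix is singular exactly when `m = 0` or
phases repeat — three distinct phases are the minimum, which the rank
tests assert. Bands are embedded in a 2× larger spectral grid with the
same frequency spacing, the ±1 bands are circularly shifted onto their
true carriers, and the enlarged spectrum is assembled with the weights of
the raised-cosine target function (1 for the 0 order, 1/2 per sideband).
A single Wiener deconvolution with the combined effective OTF — the same
filter convention and constant as the spatial pipeline — then produces
the SR image on the 2×-finer grid.

Deferring the one Wiener step until after recombination, rather than
folding per-band Wiener weights into the recombination itself, is a
deliberate design choice: it makes the two pipelines estimates of the
*same* quantity so that their agreement (Pearson r ≈ 0.9994 on bead
fields) is meaningful, and it makes the zero-carrier degenerate case
collapse exactly to widefield Wiener deconvolution of the phase-averaged
image. A per-band generalized-Wiener recombination weights the sidebands
differently from the spatial pipeline's single filter and was measured to
cap the cross-method correlation near 0.97 regardless of `w`; it is not
offered.

Carriers are handled at integer spectral pixels only. The simulator snaps
pattern periods to the nearest integer cycle count per axis by default
(≤ ~1% change at the default geometry, recorded in the pattern metadata),
so both pipelines and the analytic coefficients see exactly the same
fringe and band shifting is an exact circular roll rather than an
interpolation. Sub-pixel carriers trigger a warning and are rounded.

## Synthetic scenes and noise

The simulator replaces the microscope and defines the conditions under
which every claim is tested:

* **Bead fields** — `n` Gaussian spots of FWHM equal to the bead diameter
  (40 nm default, i.e. sub-resolution), placed by rejection sampling with
  a minimum separation (600 nm default) and border margin (600 nm); exact
  centers are recorded as ground truth. Infeasible packings fail loudly
  with the attempt count.
* **Two-point targets** — two equal spots of one-pixel FWHM about the grid
  center at a stated separation and axis; the 130 nm separation used in
  the resolution tests sits between the widefield (~200 nm) and SDR
  (~96 nm) resolutions.
* **Bar targets** — binary 50% duty-cycle stripes, a resolution-chart
  analog.
* **Uniform fields** — for fringe-contrast fidelity: a noiseless raw frame
  of a uniform object must show contrast `m·|OTF(k0)|` to 1e-3 relative.

Default illumination: orientations {0°, 60°, 120°}, period 220 nm
(near the shortest period a 200 nm-cutoff system can project, and
representable on 32.5 nm pixels), `m = 0.9`, `I0 = 300` counts so that
unit-amplitude beads peak near 1000 counts in the raw frames. The default
grid is 32.5 nm pixels, matching the camera-plane sampling of a 100×/1.49
system.

Noise is Poisson shot noise followed by additive Gaussian read noise
(default sd 2 counts), applied from a single seeded generator; identical
seeds give bit-identical stacks. These defaults are nominal sCMOS-like
values, flagged as such in the metadata — no specific camera is being
modeled. Frames are clipped at zero, which slightly biases the mean of
near-zero background pixels (≈ `σ/√(2π)` counts); mean-preservation
therefore holds only where the signal clears the noise floor.

What the simulator does **not** emulate — pattern imperfections (pitch
drift, phase errors, orientation-dependent modulation), photobleaching,
sample motion, out-of-focus background, aberrated or non-Gaussian PSFs.
Passing tests demonstrate the algebraic and numerical correctness of the
reconstructions under the stated model, not robustness to real-instrument
deviations; on real data, pattern-parameter errors would dominate.

## Resolution metrology

FWHMs are measured the way bead calibrations are normally done: an
intensity profile through the known bead center is fitted with
`A exp(−(x−x0)²/(2σ²)) + offset` by least squares and reported as
`2√(2 ln 2) σ`. The offset term absorbs reconstruction background; the
fit is invariant to affine intensity rescaling. Profiles are sampled by
bilinear interpolation at pixel/4 spacing; each bead is measured along
both image axes and the two fits averaged (the axis choice is otherwise
arbitrary for the isotropic three-orientation PSF). Bilinear interpolation
acts as a ~1-pixel triangular kernel and widens measured widths by a few
nm (widefield beads read ≈ 206 nm rather than the analytic
√(200² + 40²) ≈ 204 nm); this affects both images of a comparison equally
and is irrelevant to ratios. Beads whose analysis windows (3× widefield
FWHM) overlap are excluded and listed with reasons. Two-point
resolvability is scored as the relative depth of the intensity valley
between the two detected peaks along the joining line, 0 when the pair
merges into one peak. Method equivalence is quantified as the Pearson
correlation of border-cropped images, with the spatial result upsampled
onto the frequency pipeline's 2×-finer grid by Fourier interpolation.

## Validation problem sizes

The shipped validation uses a 512² pixel field (16.6 µm side) with 20
beads for the cross-method and FWHM-ratio measurements, 256² grids for
the two-point and fringe-contrast checks, and a 0.1 nm 1-D grid over
±1000 nm for the effective-PSF width curve. These sizes give per-bead
FWHM scatter below 1 nm and identity/oracle errors at machine precision;
larger fields change the reported values only in the fourth digit.

## Known limitations

* Pattern parameters must be exact; there is no estimation step, so the
  package cannot reconstruct stacks whose metadata is wrong or missing.
* Only the three-phase, first-harmonic (linear SIM) coefficient solution
  is implemented; nonlinear SIM harmonics would need more phases and a
  different coefficient system.
* Periodic-boundary convolution means borders are never trustworthy;
  all metrics crop them.
* The frequency pipeline requires integer-pixel carriers (guaranteed for
  simulator-snapped patterns); arbitrary experimental carriers would need
  sub-pixel shifting, which is intentionally not implemented.
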