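# sdrsim

Spatial-domain super-resolution reconstruction for structured illumination
microscopy (SIM), with a frequency-domain reference pipeline, a seeded
forward simulator, and bead-based resolution metrology.

## The problem

Linear SIM records nine raw images of a fluorescent sample — three
orientations of a sinusoidal excitation fringe, each at three phase steps —
and computationally recovers an image with roughly twice the lateral
resolution of widefield microscopy. The classical reconstruction (FDR)
works in the frequency domain: FFT all frames, separate the mixed spectral
bands, shift them to their true positions, recombine, inverse-FFT, and
deconvolve. The repeated Fourier transforms dominate the runtime and are
where most reconstruction artifacts originate.

This package implements the spatial-domain alternative (SDR). The raw
frame under the `j`-th shifted fringe is

    D_j(r) = ∫ O(r') I(r' − δ_j) H(r − r') dr',
    I(r' − δ_j) = I0 [1 + m cos(2π k0·r' + φ0 − ψ_j)],

with `O` the fluorophore distribution, `H` the (Gaussian) PSF, `I0` the
mean intensity, `m` the modulation depth, `k0` the fringe frequency and
`ψ_j = 2π k0 δ_j ∈ {0, −2π/3, +2π/3}` the phase steps. Weighting the
frames with the analytic coefficient fields

    c_j(r) = 1/(3 I0) [1 + (2/m) cos(2π k0·r + φ0 − ψ_j)]

makes the superposition `Σ_j c_j(r) D_j(r)` exactly equal to the object
convolved with a *compressed* effective PSF

    P(r) = [1 + cos(2π k0·r)] · H(r),

because the coefficients satisfy the identity
`Σ_j c_j(x) I(x' − δ_j) = 1 + cos(2π k0·(x − x'))` for every pair of
points. For a 200 nm PSF and a 200 nm fringe period, `P` has a FWHM of
about 90 nm. Summing the three orientations and applying one Wiener
deconvolution with the combined `P` yields the SR image — three pixel-wise
operations and a single FFT pair, no spectral bookkeeping. The package is
aimed at microscopists and imaging-methods developers who want a minimal,
fully testable SIM reconstruction stack that runs against synthetic ground
truth.

## Worked example

Simulate a 512×512 field of twenty 40 nm beads (32.5 nm pixels, 200 nm
PSF, fringe period ≈ 220 nm, m = 0.9), reconstruct it both ways, and
measure the resolution from the known bead positions:

```sh
sdrsim simulate --scene beads --seed 1 --out stack.tif --size 512
sdrsim reconstruct --method sdr       --in stack.tif --out sr.tif
sdrsim reconstruct --method widefield --in stack.tif --out wf.tif
sdrsim calibrate --image sr.tif --truth stack.truth.json --out sdr_report
sdrsim calibrate --image wf.tif --truth stack.truth.json --out wf_report
```

prints

```
20 beads: mean FWHM 96.0 ± 0.2 nm -> sdr_report.csv, sdr_report.json
20 beads: mean FWHM 206.3 ± 0.2 nm -> wf_report.csv, wf_report.json
```

The widefield baseline measures ≈ 206 nm (the 200 nm PSF slightly widened
by the 40 nm bead size and profile interpolation); SDR reaches ≈ 96 nm —
resolution a little better than doubled, consistent with the ≈ 90 nm
effective-PSF limit. The effective-PSF width as a function of fringe
period:

```sh
sdrsim psf-analyze --fwhm 200 --periods 200,300,400,1000000 --out curve.csv
```

```
period_nm,effective_psf_fwhm_nm
200.0,90.30
300.0,121.66
400.0,143.54
1000000.0,200.00
```

The same workflow is available as a library (`sdrsim.make_bead_field`,
`sdrsim.simulate_sim_stack`, `sdrsim.sdr_reconstruct`,
`sdrsim.fdr_reconstruct`, `sdrsim.bead_fwhm_report`, …); see the
docstrings and `docs/methods.md`.

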