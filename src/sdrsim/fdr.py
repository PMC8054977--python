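"""Frequency-domain reconstruction (FDR): the classical reference pipeline.

The standard linear workflow: Fourier-transform the nine raw frames,
separate each orientation's three spectra into the 0 and ±1 order object
bands by inverting the 3x3 phase-mixing system, translate the ±1 bands
back to their true positions on a 2x zero-padded spectral grid, recombine
them into the enlarged spectrum, apply the final Wiener deconvolution
(the same filter convention as the spatial pipeline), and
inverse-transform.

This module is a faithful baseline implementation of that standard
workflow, used as the in-repo comparator for the spatial-domain
reconstruction's equivalence tests. Pattern carriers are assumed to sit on
integer spectral pixels (the simulator snaps periods so by default), which
makes band translation an exact circular shift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .errors import (
    FrequencyRangeError,
    InvalidParameterError,
    ShapeError,
    SingularMatrixError,
)
from .grid import Grid2D
from .optics import GaussianPSF, SinusoidPattern, gaussian_psf_image, otf_from_psf
from .sdr import DEFAULT_WIENER_W, ReconResult
from .simulate import SIMStack, carrier_pixels

__all__ = [
    "SpectrumBands",
    "mixing_matrix",
    "separate_bands",
    "shift_and_recombine",
    "fdr_reconstruct",
    "pad_spectrum",
    "fourier_upsample",
]

_COND_LIMIT = 1e10


@dataclass(frozen=True)
class SpectrumBands:
    """Separated spectral components of one orientation.

    ``band0`` holds the widefield (0-order) object spectrum times the OTF;
    ``band_plus``/``band_minus`` hold the object spectrum displaced by
    -/+ the pattern frequency, i.e. ``O(k -/+ k0) * OTF(k)``. All three are
    stored in standard ``numpy.fft`` layout on the raw-frame grid.
    ``carrier`` is the pattern frequency in integer spectral pixels
    (cycles down rows, cycles across columns).
    """

    band0: np.ndarray
    band_plus: np.ndarray
    band_minus: np.ndarray
    carrier: tuple[int, int]
    grid: Grid2D

    def __post_init__(self) -> None:
        shapes = {self.band0.shape, self.band_plus.shape, self.band_minus.shape}
        if shapes != {self.grid.shape}:
            raise ShapeError("band spectra must all share the grid shape")


def mixing_matrix(
    modulation_depth: float,
    phase_shifts_rad,
    initial_phase_rad: float = 0.0,
    mean_intensity: float = 1.0,
) -> np.ndarray:
    """The per-frequency phase-mixing system of linear structured illumination.

    Row j maps the band vector ``[B0, B+, B-]`` to frame spectrum j:
    ``I0 * [1, (m/2) e^{+i(phi0-psi_j)}, (m/2) e^{-i(phi0-psi_j)}]``.
    The system is full rank only for m > 0 and at least three distinct
    phases — the minimal number of phase steps is three.
    """
    shifts = np.asarray(list(phase_shifts_rad), dtype=float)
    rel = initial_phase_rad - shifts
    m = modulation_depth
    rows = np.stack(
        [np.ones_like(rel), (m / 2.0) * np.exp(1j * rel), (m / 2.0) * np.exp(-1j * rel)],
        axis=1,
    )
    return mean_intensity * rows


def separate_bands(stack: SIMStack, orientation_index: int) -> SpectrumBands:
    """Unmix one orientation's three frame spectra into object bands.

    Solves, per frequency pixel, the 3x3 linear system given by
    :func:`mixing_matrix`; raises :class:`SingularMatrixError` when the
    system is rank deficient (m = 0 or repeated phases).
    """
    pattern = stack.patterns[orientation_index]
    if pattern.n_phases != 3:
        raise SingularMatrixError(
            f"band separation needs 3 phases, got {pattern.n_phases}"
        )
    matrix = mixing_matrix(
        pattern.modulation_depth,
        pattern.phase_shifts_rad,
        pattern.initial_phase_rad,
        pattern.mean_intensity,
    )
    if np.linalg.cond(matrix) > _COND_LIMIT:
        raise SingularMatrixError(
            "phase-mixing matrix is singular (m = 0 or repeated phase shifts)"
        )
    inv = np.linalg.inv(matrix)
    spectra = np.stack([np.fft.fft2(f) for f in stack.orientation_frames(orientation_index)])
    bands = np.einsum("bj,jxy->bxy", inv, spectra)

    cy, cx = carrier_pixels(pattern, stack.grid)
    cy_i, cx_i = round(cy), round(cx)
    if abs(cy - cy_i) > 1e-3 or abs(cx - cx_i) > 1e-3:
        import warnings

        warnings.warn(
            f"pattern carrier ({cy:.3f}, {cx:.3f}) is not on integer spectral pixels; "
            "rounding — snap the pattern to the grid for exact band shifts",
            stacklevel=2,
        )
    return SpectrumBands(
        band0=bands[0],
        band_plus=bands[1],
        band_minus=bands[2],
        carrier=(cy_i, cx_i),
        grid=stack.grid,
    )


def pad_spectrum(spectrum: np.ndarray, factor: int = 2) -> np.ndarray:
    """Embed a spectrum (numpy.fft layout) centered in a ``factor``-times
    larger spectral grid of identical frequency spacing."""
    if factor < 1:
        raise InvalidParameterError("pad factor must be >= 1")
    n0, n1 = spectrum.shape
    out = np.zeros((factor * n0, factor * n1), dtype=complex)
    r0 = (factor * n0 - n0) // 2
    r1 = (factor * n1 - n1) // 2
    out[r0 : r0 + n0, r1 : r1 + n1] = np.fft.fftshift(spectrum)
    return np.fft.ifftshift(out)


def fourier_upsample(image: np.ndarray, factor: int = 2) -> np.ndarray:
    """Band-limited (Fourier) interpolation of an image onto a grid
    ``factor`` times finer, preserving intensity values."""
    spec = np.fft.fft2(np.asarray(image, dtype=float))
    return np.fft.ifft2(pad_spectrum(spec, factor)).real * factor**2


def shift_and_recombine(
    bands_list,
    psf: GaussianPSF,
    grid: Grid2D,
    wiener_w: float = DEFAULT_WIENER_W,
    *,
    pad_factor: int = 2,
    apodize: bool = False,
) -> np.ndarray:
    """Translate ±1 bands to their true spectral positions, recombine, and
    apply the final Wiener deconvolution.

    All bands are embedded in a ``pad_factor``-times larger spectral grid
    (same frequency spacing, so integer carriers shift exactly), each ±1
    band is circularly shifted by -/+ its carrier, and the enlarged
    spectrum is assembled with the target-function weights of the
    raised-cosine expansion — 1 for the 0 order and 1/2 for each ±1 order:

        S(k) = sum_d [ B0_d(k) + (1/2) B+_d(k + c_d) + (1/2) B-_d(k - c_d) ]
             = O(k) * sum_d [ OTF(k) + (1/2) OTF(k ± c_d) ],

    i.e. the object spectrum seen through the combined effective OTF. A
    single Wiener deconvolution with that same effective OTF — the matched
    counterpart of the spatial pipeline's final step — then compensates
    the OTF:

        R(k) = S(k) conj(OTF_eff) / (|OTF_eff|^2 + w^2).

    The inverse FFT's real part, clipped at zero, is the SR image on a
    grid ``pad_factor`` times finer than the input. When every carrier is
    zero this reduces exactly (up to a constant scale) to widefield Wiener
    deconvolution of the phase-averaged image.
    """
    if not wiener_w > 0:
        raise InvalidParameterError("wiener_w must be positive")
    fine_grid = Grid2D(
        pad_factor * grid.n_rows, pad_factor * grid.n_cols, grid.pixel_size_nm / pad_factor
    )
    otf_pad = otf_from_psf(gaussian_psf_image(psf, fine_grid, warn_truncation=False))
    half = (pad_factor * grid.n_rows // 2, pad_factor * grid.n_cols // 2)

    combined = np.zeros(fine_grid.shape, dtype=complex)
    otf_eff = np.zeros(fine_grid.shape, dtype=complex)
    for bands in bands_list:
        cy, cx = bands.carrier
        if abs(cy) >= half[0] or abs(cx) >= half[1]:
            raise FrequencyRangeError(
                f"carrier ({cy}, {cx}) outside padded spectral support {half}"
            )
        for band, sign, weight in (
            (bands.band0, 0, 1.0),
            (bands.band_plus, +1, 0.5),
            (bands.band_minus, -1, 0.5),
        ):
            padded = pad_spectrum(band, pad_factor)
            shift = (-sign * cy, -sign * cx)
            combined += weight * np.roll(padded, shift, axis=(0, 1))
            otf_eff += weight * np.roll(otf_pad, shift, axis=(0, 1))
    otf_eff /= otf_eff[0, 0].real  # unit DC, matching the spatial pipeline's w scale
    filtered = combined * np.conj(otf_eff) / (np.abs(otf_eff) ** 2 + wiener_w**2)
    if apodize:
        filtered *= _triangular_apodization(fine_grid.shape)
    field = np.fft.ifft2(filtered) * pad_factor**2
    scale = np.max(np.abs(field))
    if scale > 0 and np.max(np.abs(field.imag)) > 1e-9 * scale:
        import warnings

        warnings.warn("recombined image has unexpectedly large imaginary part", stacklevel=2)
    return np.clip(field.real, 0.0, None)


def _triangular_apodization(shape: tuple[int, int]) -> np.ndarray:
    """Radial cone from 1 at DC to 0 at the padded-grid Nyquist corner."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    r = np.hypot(fy / 0.5, fx / 0.5)
    return np.clip(1.0 - r / np.sqrt(2.0), 0.0, 1.0)


def fdr_reconstruct(
    stack: SIMStack,
    wiener_w: float = DEFAULT_WIENER_W,
    *,
    pad_factor: int = 2,
    apodize: bool = False,
) -> ReconResult:
    """Full frequency-domain pipeline over all three orientations.

    The output grid is ``pad_factor`` times finer than the raw frames.
    """
    bands = [separate_bands(stack, d) for d in range(3)]
    image = shift_and_recombine(
        bands, stack.psf, stack.grid, wiener_w, pad_factor=pad_factor, apodize=apodize
    )
    fine_grid = Grid2D(
        pad_factor * stack.grid.n_rows,
        pad_factor * stack.grid.n_cols,
        stack.grid.pixel_size_nm / pad_factor,
    )
    params: dict[str, Any] = {
        "patterns": stack.patterns,
        "psf_fwhm_nm": stack.psf.fwhm_nm,
        "pixel_size_nm": stack.grid.pixel_size_nm,
        "noise_seed": None if stack.noise is None else stack.noise.seed,
        "wiener_w": wiener_w,
        "pad_factor": pad_factor,
        "apodize": apodize,
        "unclipped": image,
    }
    return ReconResult(
        sr_image=image, grid=fine_grid, method="fdr", effective_psf=None, params=params
    )
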