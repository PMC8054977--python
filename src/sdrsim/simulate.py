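"""Forward simulator: synthetic scenes and 9-frame raw SIM stacks.

Raw frames follow the linear image-formation model

    D_j(r) = sum_r' O(r') * I_j(r') * H(r - r'),

evaluated by FFT convolution with periodic boundaries, optionally followed
by Poisson shot noise and additive Gaussian read noise. A stack is three
illumination orientations times three phase steps, orientation-major.

Scenes emulate the standard calibration targets of super-resolution
microscopy: sparse sub-diffraction bead fields, two-point separation
targets, bar (resolution-chart) targets and uniform fields. Scene content
is kept away from the raster border (the generators enforce a margin) so
that the periodic convolution does not wrap structure into the analysis
region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import InvalidParameterError, PackingError, ShapeError
from .grid import Grid2D
from .optics import (
    FWHM_TO_SIGMA,
    GaussianPSF,
    SinusoidPattern,
    gaussian_psf_image,
    illumination_image,
)

__all__ = [
    "SceneObject",
    "NoiseModel",
    "SIMStack",
    "make_bead_field",
    "make_two_point",
    "make_point_source",
    "make_bar_target",
    "make_uniform",
    "default_patterns",
    "snap_pattern_to_grid",
    "carrier_pixels",
    "simulate_sim_stack",
    "widefield_image",
    "fft_convolve",
    "DEFAULT_PERIOD_NM",
    "DEFAULT_ORIENTATIONS_DEG",
    "DEFAULT_MODULATION",
    "DEFAULT_MEAN_INTENSITY",
]

#: Default illumination: near the smallest period a 200 nm-cutoff system
#: can project, representable on 32.5 nm pixels.
DEFAULT_PERIOD_NM = 220.0
DEFAULT_ORIENTATIONS_DEG = (0.0, 60.0, 120.0)
DEFAULT_MODULATION = 0.9
#: Nominal photon scale: unit-amplitude 40 nm beads peak near 1000 counts.
DEFAULT_MEAN_INTENSITY = 300.0


@dataclass(frozen=True)
class SceneObject:
    """A ground-truth fluorophore-density map plus its structured truth.

    ``truth`` carries the generator's exact description: bead centers and
    amplitudes in physical nm coordinates, bar geometry, or "uniform".
    """

    image: np.ndarray
    grid: Grid2D
    truth: dict[str, Any]

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        object.__setattr__(self, "image", img)
        if img.shape != self.grid.shape:
            raise ShapeError(f"image shape {img.shape} != grid shape {self.grid.shape}")
        if not np.all(np.isfinite(img)) or np.any(img < 0):
            raise InvalidParameterError("scene image must be nonnegative and finite")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise plus Gaussian read noise.

    Identical seeds yield bit-identical realizations. The defaults are
    nominal sCMOS-like values, flagged as such in stack metadata.
    """

    poisson_enabled: bool = True
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise InvalidParameterError("read_noise_sd must be >= 0")

    def apply(self, frames: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        out = np.asarray(frames, dtype=float)
        if self.poisson_enabled:
            out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
        if self.read_noise_sd > 0:
            out = out + rng.normal(0.0, self.read_noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class SIMStack:
    """Nine raw frames (3 orientations x 3 phases, orientation-major) plus
    the acquisition metadata needed to reconstruct them."""

    frames: np.ndarray
    patterns: tuple[SinusoidPattern, SinusoidPattern, SinusoidPattern]
    psf: GaussianPSF
    grid: Grid2D
    noise: NoiseModel | None = None
    scene_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "patterns", tuple(self.patterns))
        if len(self.patterns) != 3:
            raise ShapeError(f"expected 3 patterns, got {len(self.patterns)}")
        if frames.shape != (9, *self.grid.shape):
            raise ShapeError(
                f"expected frames of shape (9, {self.grid.n_rows}, {self.grid.n_cols}), "
                f"got {frames.shape}"
            )
        if np.any(frames < 0):
            raise InvalidParameterError("raw frames must be nonnegative")

    def frame(self, orientation_index: int, phase_index: int) -> np.ndarray:
        return self.frames[3 * orientation_index + phase_index]

    def orientation_frames(self, orientation_index: int) -> np.ndarray:
        if not 0 <= orientation_index < 3:
            raise IndexError(f"orientation_index {orientation_index} out of range")
        return self.frames[3 * orientation_index : 3 * orientation_index + 3]


def _render_spots(
    grid: Grid2D,
    centers_nm: np.ndarray,
    amplitudes: np.ndarray,
    spot_fwhm_nm: float,
) -> np.ndarray:
    """Sum of peak-normalized Gaussian spots at subpixel centers."""
    sigma = spot_fwhm_nm / FWHM_TO_SIGMA
    image = np.zeros(grid.shape)
    x, y = grid.x_nm, grid.y_nm
    for (cx, cy), amp in zip(centers_nm, amplitudes):
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        image += amp * np.exp(-d2 / (2.0 * sigma**2))
    return image


def make_bead_field(
    grid: Grid2D,
    n_beads: int = 20,
    bead_diameter_nm: float = 40.0,
    min_separation_nm: float = 600.0,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    margin_nm: float = 600.0,
    max_attempts_per_bead: int = 2000,
) -> SceneObject:
    """Sparse field of sub-diffraction beads at random positions.

    Beads are rendered as Gaussian spots of FWHM equal to the bead diameter
    (40 nm default), i.e. effectively point emitters for a 200 nm PSF.
    Positions are drawn uniformly, rejecting draws closer than
    ``min_separation_nm`` to an accepted bead or ``margin_nm`` to the
    border; an infeasible packing raises :class:`PackingError`.
    """
    if n_beads < 1:
        raise InvalidParameterError("n_beads must be >= 1")
    if bead_diameter_nm <= 0:
        raise InvalidParameterError("bead_diameter_nm must be positive")
    rng = np.random.default_rng(seed)
    height, width = grid.extent_nm
    i0, j0 = grid.origin
    x_lo = -j0 * grid.pixel_size_nm + margin_nm
    x_hi = (grid.n_cols - 1 - j0) * grid.pixel_size_nm - margin_nm
    y_lo = -i0 * grid.pixel_size_nm + margin_nm
    y_hi = (grid.n_rows - 1 - i0) * grid.pixel_size_nm - margin_nm
    if x_hi <= x_lo or y_hi <= y_lo:
        raise PackingError("margin leaves no room for beads on this grid")

    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_bead * n_beads
    while len(centers) < n_beads:
        if attempts >= budget:
            raise PackingError(
                f"placed {len(centers)}/{n_beads} beads after {attempts} attempts; "
                f"min_separation_nm={min_separation_nm} is infeasible on this grid"
            )
        attempts += 1
        cx = rng.uniform(x_lo, x_hi)
        cy = rng.uniform(y_lo, y_hi)
        if all(math.hypot(cx - px, cy - py) >= min_separation_nm for px, py in centers):
            centers.append((cx, cy))

    centers_arr = np.asarray(centers)
    amps = np.full(n_beads, float(amplitude))
    image = _render_spots(grid, centers_arr, amps, bead_diameter_nm)
    truth = {
        "kind": "beads",
        "centers_nm": [list(c) for c in centers],
        "amplitudes": amps.tolist(),
        "bead_diameter_nm": float(bead_diameter_nm),
        "min_separation_nm": float(min_separation_nm),
        "seed": int(seed),
    }
    return SceneObject(image=image, grid=grid, truth=truth)


def make_two_point(
    grid: Grid2D,
    separation_nm: float,
    axis_deg: float = 0.0,
    *,
    amplitude: float = 1.0,
    spot_fwhm_nm: float | None = None,
) -> SceneObject:
    """Two equal point emitters centered on the grid, separated along an axis.

    Spots default to a FWHM of one pixel so that subpixel separations are
    representable; they remain far below the diffraction limit.
    """
    if separation_nm < grid.pixel_size_nm:
        raise InvalidParameterError(
            f"separation_nm={separation_nm} is below one pixel ({grid.pixel_size_nm} nm)"
        )
    theta = math.radians(axis_deg)
    half = separation_nm / 2.0
    c1 = (half * math.cos(theta), half * math.sin(theta))
    c2 = (-c1[0], -c1[1])
    for cx, cy in (c1, c2):
        if not grid.contains_nm(cx, cy, margin_nm=0.0):
            raise InvalidParameterError(
                f"separation_nm={separation_nm} places an emitter outside the grid"
            )
    if spot_fwhm_nm is None:
        spot_fwhm_nm = grid.pixel_size_nm
    centers = np.asarray([c1, c2])
    image = _render_spots(grid, centers, np.full(2, float(amplitude)), spot_fwhm_nm)
    truth = {
        "kind": "two-point",
        "centers_nm": [list(c1), list(c2)],
        "separation_nm": float(separation_nm),
        "axis_deg": float(axis_deg),
        "spot_fwhm_nm": float(spot_fwhm_nm),
    }
    return SceneObject(image=image, grid=grid, truth=truth)


def make_point_source(grid: Grid2D, amplitude: float = 1.0) -> SceneObject:
    """Single-pixel delta emitter at the grid's origin pixel (exact, not a
    rendered spot) — the oracle scene for PSF identities."""
    image = np.zeros(grid.shape)
    image[grid.origin] = float(amplitude)
    truth = {"kind": "point", "centers_nm": [[0.0, 0.0]], "amplitude": float(amplitude)}
    return SceneObject(image=image, grid=grid, truth=truth)


def make_bar_target(
    grid: Grid2D,
    bar_period_nm: float,
    n_bars: int = 3,
    orientation_deg: float = 0.0,
    *,
    amplitude: float = 1.0,
) -> SceneObject:
    """Alternating on/off bars at 50% duty cycle (resolution-chart analog).

    ``orientation_deg`` is the direction across the bars (the bar stripes
    run perpendicular to it). The target spans ``n_bars`` periods centered
    on the grid.
    """
    if bar_period_nm < 2.0 * grid.pixel_size_nm:
        raise InvalidParameterError(
            f"bar_period_nm={bar_period_nm} is below two pixels "
            f"({2 * grid.pixel_size_nm} nm): bars would be sub-pixel"
        )
    if n_bars < 1:
        raise InvalidParameterError("n_bars must be >= 1")
    theta = math.radians(orientation_deg)
    u = math.cos(theta) * grid.x_nm + math.sin(theta) * grid.y_nm
    v = -math.sin(theta) * grid.x_nm + math.cos(theta) * grid.y_nm
    span = n_bars * bar_period_nm
    u0 = u + span / 2.0  # bar pattern starts "on" at the left edge of the target
    in_target = (u0 >= 0) & (u0 < span) & (np.abs(v) <= span / 2.0)
    on = np.mod(u0, bar_period_nm) < bar_period_nm / 2.0
    image = np.where(in_target & on, float(amplitude), 0.0)
    truth = {
        "kind": "bars",
        "bar_period_nm": float(bar_period_nm),
        "n_bars": int(n_bars),
        "orientation_deg": float(orientation_deg),
        "amplitude": float(amplitude),
    }
    return SceneObject(image=image, grid=grid, truth=truth)


def make_uniform(grid: Grid2D, level: float = 1.0) -> SceneObject:
    """Spatially uniform fluorophore density."""
    if level < 0:
        raise InvalidParameterError("level must be nonnegative")
    return SceneObject(
        image=np.full(grid.shape, float(level)), grid=grid, truth={"kind": "uniform", "level": float(level)}
    )


def carrier_pixels(pattern: SinusoidPattern, grid: Grid2D) -> tuple[float, float]:
    """Pattern frequency in spectral-pixel units: (cycles down rows, cycles
    across columns) over the full raster. Integer values mean the fringe
    tiles the periodic grid exactly."""
    kx, ky = pattern.wavevector_cyc_per_nm
    height, width = grid.extent_nm
    return (ky * height, kx * width)


def snap_pattern_to_grid(pattern: SinusoidPattern, grid: Grid2D) -> SinusoidPattern:
    """Snap a pattern's wavevector to the nearest integer spectral pixel.

    Rounds the per-axis cycle counts over the raster to integers and
    recomputes period and orientation, so that FFT-based simulation,
    band separation and the analytic coefficient fields all see exactly
    the same fringe. The relative change is O(1 / cycles) and is recorded
    in the returned pattern's period/orientation fields.
    """
    cy, cx = carrier_pixels(pattern, grid)
    cy_i, cx_i = round(cy), round(cx)
    if cy_i == 0 and cx_i == 0:
        raise InvalidParameterError(
            f"pattern period {pattern.period_nm} nm exceeds the grid extent; cannot snap"
        )
    height, width = grid.extent_nm
    ky = cy_i / height
    kx = cx_i / width
    k = math.hypot(kx, ky)
    return replace(
        pattern,
        period_nm=1.0 / k,
        orientation_deg=math.degrees(math.atan2(ky, kx)),
    )


def default_patterns(
    grid: Grid2D | None = None,
    *,
    period_nm: float = DEFAULT_PERIOD_NM,
    orientations_deg: tuple[float, ...] = DEFAULT_ORIENTATIONS_DEG,
    modulation_depth: float = DEFAULT_MODULATION,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    initial_phase_rad: float = 0.0,
    snap: bool = True,
) -> tuple[SinusoidPattern, ...]:
    """The standard three-orientation pattern set (0/60/120 deg, T=220 nm,
    m=0.9). When a grid is given and ``snap`` is true, each pattern is
    snapped to integer spectral pixels of that grid."""
    pats = tuple(
        SinusoidPattern(
            mean_intensity=mean_intensity,
            modulation_depth=modulation_depth,
            period_nm=period_nm,
            orientation_deg=theta,
            initial_phase_rad=initial_phase_rad,
        )
        for theta in orientations_deg
    )
    if grid is not None and snap:
        pats = tuple(snap_pattern_to_grid(p, grid) for p in pats)
    return pats


def fft_convolve(image: np.ndarray, kernel_centered: np.ndarray) -> np.ndarray:
    """Circular convolution with a kernel centered on the origin pixel."""
    if image.shape != kernel_centered.shape:
        raise ShapeError(f"image {image.shape} and kernel {kernel_centered.shape} differ")
    k = np.fft.ifftshift(kernel_centered)
    return np.fft.ifft2(np.fft.fft2(image) * np.fft.fft2(k)).real


def simulate_sim_stack(
    obj: SceneObject,
    patterns,
    psf: GaussianPSF,
    noise: NoiseModel | None = None,
) -> SIMStack:
    """Image a scene through the sinusoidal-illumination forward model.

    Each frame is ``convolve(O * I_{d,j}, H)`` (FFT, periodic boundaries),
    then optional Poisson sampling plus Gaussian read noise, clipped at 0.
    Frames are ordered orientation-major, phase-minor.
    """
    patterns = tuple(patterns)
    if len(patterns) != 3:
        raise ShapeError(f"expected 3 patterns, got {len(patterns)}")
    i0s = {p.mean_intensity for p in patterns}
    ms = {p.modulation_depth for p in patterns}
    if len(i0s) > 1 or len(ms) > 1:
        import warnings

        warnings.warn("patterns do not share mean_intensity/modulation_depth", stacklevel=2)
    grid = obj.grid
    h = gaussian_psf_image(psf, grid, warn_truncation=True)
    otf_unnorm = np.fft.fft2(np.fft.ifftshift(h))
    frames = np.empty((9, *grid.shape))
    for d, pat in enumerate(patterns):
        for j in range(3):
            illum = illumination_image(pat, j, grid)
            product = obj.image * illum
            frames[3 * d + j] = np.fft.ifft2(np.fft.fft2(product) * otf_unnorm).real
    frames = np.clip(frames, 0.0, None)
    if noise is not None:
        frames = noise.apply(frames)
    return SIMStack(
        frames=frames, patterns=patterns, psf=psf, grid=grid, noise=noise, scene_truth=obj.truth
    )


def widefield_image(stack: SIMStack) -> np.ndarray:
    """The diffraction-limited baseline: phase-average of the raw frames.

    The three 120-degree phase steps cancel the fringe exactly, so this
    equals uniform-illumination imaging at intensity I0: ``I0 * (O * H)``.
    """
    return stack.frames.mean(axis=0)
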