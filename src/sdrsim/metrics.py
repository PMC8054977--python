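"""Resolution metrology: bead FWHM fits, two-point resolvability, similarity.

The evaluation mirrors the standard bead-calibration workflow: intensity
profiles are extracted through known emitter positions, fitted with a
Gaussian-plus-offset model, and reported as FWHMs; two-point targets are
scored by the contrast of the intensity dip between the peaks; and pairs
of reconstructions are compared by the Pearson correlation of their
border-cropped images.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .errors import (
    FitFailureError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .grid import Grid2D
from .optics import FWHM_TO_SIGMA

__all__ = [
    "FWHMReport",
    "fit_fwhm_profile",
    "bead_fwhm_report",
    "two_point_dip",
    "image_similarity",
    "extract_profile",
]


@dataclass
class FWHMReport:
    """Per-bead Gaussian-fit FWHMs and their aggregates.

    ``per_bead`` rows are ``(center_nm, fitted_fwhm_nm, fit_residual)``;
    ``excluded`` lists ``(center_nm, reason)`` for beads left out (e.g.
    overlapping analysis windows).
    """

    per_bead: list[tuple[tuple[float, float], float, float]]
    excluded: list[tuple[tuple[float, float], str]] = field(default_factory=list)

    @property
    def n_beads(self) -> int:
        return len(self.per_bead)

    @property
    def fwhms_nm(self) -> np.ndarray:
        return np.asarray([b[1] for b in self.per_bead], dtype=float)

    @property
    def mean_fwhm_nm(self) -> float:
        return float(self.fwhms_nm.mean()) if self.n_beads else float("nan")

    @property
    def sd_fwhm_nm(self) -> float:
        return float(self.fwhms_nm.std(ddof=1)) if self.n_beads > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "n_beads": self.n_beads,
            "mean_fwhm_nm": self.mean_fwhm_nm,
            "sd_fwhm_nm": self.sd_fwhm_nm,
            "per_bead": [
                {"center_nm": list(c), "fwhm_nm": f, "residual": r}
                for c, f, r in self.per_bead
            ],
            "excluded": [{"center_nm": list(c), "reason": r} for c, r in self.excluded],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["center_x_nm", "center_y_nm", "fwhm_nm", "residual"])
            for (cx, cy), f, r in self.per_bead:
                writer.writerow([cx, cy, f, r])


def _gauss_offset(x, amplitude, x0, sigma, offset):
    return amplitude * np.exp(-((x - x0) ** 2) / (2.0 * sigma**2)) + offset


def fit_fwhm_profile(profile: np.ndarray, sample_spacing_nm: float) -> float:
    """FWHM of a single-peaked 1-D profile by least-squares Gaussian fit.

    Fits ``A exp(-(x - x0)^2 / (2 sigma^2)) + offset`` (the offset absorbs
    reconstruction background) and returns ``2 sqrt(2 ln 2) sigma``. The
    result is invariant to affine rescaling of the profile.
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 7:
        raise InvalidParameterError("profile must be 1-D with at least 7 samples")
    if not sample_spacing_nm > 0:
        raise InvalidParameterError("sample_spacing_nm must be positive")
    x = np.arange(y.size) * sample_spacing_nm
    lo, hi = y.min(), y.max()
    if hi - lo <= 0 or (hi - lo) < 1e-12 * max(abs(hi), 1.0):
        raise FitFailureError("profile is flat: no peak to fit")
    # moment-based initial guess over the above-offset mass
    w = np.clip(y - lo, 0.0, None)
    x0 = float((w * x).sum() / w.sum())
    var = float((w * (x - x0) ** 2).sum() / w.sum())
    sigma0 = max(math.sqrt(var), sample_spacing_nm / 2.0)
    p0 = [hi - lo, x0, sigma0, lo]
    try:
        popt, _ = optimize.curve_fit(
            _gauss_offset,
            x,
            y,
            p0=p0,
            maxfev=10000,
            bounds=([0.0, x[0] - x[-1], sample_spacing_nm / 10.0, -np.inf],
                    [np.inf, 2 * x[-1], 10.0 * (x[-1] - x[0]), np.inf]),
        )
    except (RuntimeError, ValueError) as exc:
        residual = float(np.sqrt(np.mean((_gauss_offset(x, *p0) - y) ** 2)))
        raise FitFailureError(
            f"Gaussian fit did not converge (rms residual at start {residual:.3g})"
        ) from exc
    return float(FWHM_TO_SIGMA * popt[2])


def extract_profile(
    image: np.ndarray,
    grid: Grid2D,
    start_nm: tuple[float, float],
    stop_nm: tuple[float, float],
    *,
    oversample: int = 4,
) -> tuple[np.ndarray, float]:
    """Bilinear line profile between two physical points.

    Returns ``(samples, spacing_nm)``; samples are spaced
    ``pixel_size / oversample`` apart along the segment.
    """
    x0, y0 = start_nm
    x1, y1 = stop_nm
    length = math.hypot(x1 - x0, y1 - y0)
    if length <= 0:
        raise InvalidParameterError("profile endpoints coincide")
    spacing = grid.pixel_size_nm / oversample
    n = max(int(round(length / spacing)) + 1, 7)
    t = np.linspace(0.0, 1.0, n)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    i0, j0 = grid.origin
    rows = ys / grid.pixel_size_nm + i0
    cols = xs / grid.pixel_size_nm + j0
    samples = ndimage.map_coordinates(
        np.asarray(image, dtype=float), np.stack([rows, cols]), order=1, mode="nearest"
    )
    return samples, length / (n - 1)


def bead_fwhm_report(
    image: np.ndarray,
    grid: Grid2D,
    truth_centers_nm,
    window_nm: float = 600.0,
    *,
    oversample: int = 4,
) -> FWHMReport:
    """Gaussian-fit FWHM of every isolated bead in an image.

    For each truth center, horizontal and vertical profiles of total
    length ``window_nm`` are extracted through the center and fitted
    separately; the bead's FWHM is the mean of the two axis fits. Beads
    whose analysis windows overlap another bead's, or that fall too close
    to the border, are excluded with a logged reason.
    """
    centers = [tuple(map(float, c)) for c in truth_centers_nm]
    half = window_nm / 2.0
    report = FWHMReport(per_bead=[])
    for idx, (cx, cy) in enumerate(centers):
        reason = None
        if not grid.contains_nm(cx, cy, margin_nm=half):
            reason = "window extends past image border"
        else:
            for other_idx, (ox, oy) in enumerate(centers):
                if other_idx != idx and math.hypot(ox - cx, oy - cy) < window_nm:
                    reason = f"window overlaps bead {other_idx}"
                    break
        if reason is not None:
            report.excluded.append(((cx, cy), reason))
            continue
        fwhms = []
        residuals = []
        try:
            for dx, dy in ((half, 0.0), (0.0, half)):
                samples, spacing = extract_profile(
                    image, grid, (cx - dx, cy - dy), (cx + dx, cy + dy), oversample=oversample
                )
                fwhms.append(fit_fwhm_profile(samples, spacing))
                residuals.append(_fit_residual(samples, spacing))
        except FitFailureError as exc:
            report.excluded.append(((cx, cy), f"fit failed: {exc}"))
            continue
        report.per_bead.append(
            ((cx, cy), float(np.mean(fwhms)), float(np.nanmean(residuals)))
        )
    return report


def _fit_residual(profile: np.ndarray, spacing_nm: float) -> float:
    """Normalized rms residual of the Gaussian+offset fit to a profile."""
    y = np.asarray(profile, dtype=float)
    x = np.arange(y.size) * spacing_nm
    lo, hi = y.min(), y.max()
    w = np.clip(y - lo, 0.0, None)
    x0 = float((w * x).sum() / max(w.sum(), 1e-30))
    var = float((w * (x - x0) ** 2).sum() / max(w.sum(), 1e-30))
    p0 = [hi - lo, x0, max(math.sqrt(max(var, 0.0)), spacing_nm / 2.0), lo]
    try:
        popt, _ = optimize.curve_fit(_gauss_offset, x, y, p0=p0, maxfev=10000)
        rms = float(np.sqrt(np.mean((_gauss_offset(x, *popt) - y) ** 2)))
    except (RuntimeError, ValueError):
        return float("nan")
    span = hi - lo
    return rms / span if span > 0 else float("nan")


def two_point_dip(
    image: np.ndarray,
    grid: Grid2D,
    truth_centers_nm,
    *,
    extend_factor: float = 1.6,
    oversample: int = 4,
) -> float:
    """Resolvability score of a two-emitter target, in [0, 1].

    The intensity profile is taken along the line joining the two truth
    centers (extended beyond them so the peaks are interior). With two
    detected peaks and a valley between them the score is
    ``(min(peak1, peak2) - valley) / min(peak1, peak2)``; when the profile
    shows a single merged peak (unresolved) the score is 0.
    """
    centers = [tuple(map(float, c)) for c in truth_centers_nm]
    if len(centers) != 2:
        raise InvalidParameterError("two_point_dip needs exactly two centers")
    (x0, y0), (x1, y1) = centers
    if math.hypot(x1 - x0, y1 - y0) <= 0:
        raise InvalidParameterError("the two centers coincide")
    mx, my = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    ex = (x0 - mx) * extend_factor * 2.0
    ey = (y0 - my) * extend_factor * 2.0
    samples, _ = extract_profile(
        image, grid, (mx + ex, my + ey), (mx - ex, my - ey), oversample=oversample
    )
    peaks, _ = signal.find_peaks(samples)
    if peaks.size < 2:
        return 0.0
    # the two strongest interior peaks, in positional order
    strongest = peaks[np.argsort(samples[peaks])[-2:]]
    lo_i, hi_i = sorted(int(p) for p in strongest)
    if hi_i - lo_i < 2:
        return 0.0
    valley = float(samples[lo_i:hi_i + 1].min())
    ref = float(min(samples[lo_i], samples[hi_i]))
    if ref <= 0 or valley >= ref:
        return 0.0
    return (ref - valley) / ref


def image_similarity(a: np.ndarray, b: np.ndarray, crop_margin: int = 0) -> float:
    """Pearson correlation of two images after symmetric border cropping.

    Images must share the (cropped) shape; intensity normalization is
    irrelevant to the statistic. A constant image raises
    :class:`UndefinedCorrelationError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if crop_margin < 0:
        raise InvalidParameterError("crop_margin must be >= 0")
    if crop_margin:
        a = a[crop_margin:-crop_margin, crop_margin:-crop_margin]
        b = b[crop_margin:-crop_margin, crop_margin:-crop_margin]
    if a.shape != b.shape:
        raise InvalidParameterError(f"shapes differ after cropping: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise InvalidParameterError("cropping removed the whole image")
    av = a.ravel() - a.mean()
    bv = b.ravel() - b.mean()
    na, nb = np.linalg.norm(av), np.linalg.norm(bv)
    if na == 0 or nb == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant image")
    return float(np.dot(av, bv) / (na * nb))
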