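"""File formats: 9-page float TIFF stacks with JSON metadata sidecars.

A raw stack on disk is a multi-page 32-bit-float TIFF (9 pages,
orientation-major, phase-minor) plus a human-diffable JSON sidecar
carrying everything needed to reconstruct it: pixel size, PSF FWHM, the
three illumination-pattern records and the noise model (including its
seed). Reconstruction results are single-page TIFFs with a provenance
sidecar. Every artifact is reproducible bit-for-bit from its own sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from . import __version__
from .errors import MetadataError, ShapeError
from .grid import Grid2D
from .optics import GaussianPSF, SinusoidPattern
from .simulate import NoiseModel, SIMStack

__all__ = [
    "SCHEMA_VERSION",
    "FRAME_ORDER",
    "stack_metadata",
    "read_stack",
    "write_stack",
    "write_result",
    "default_sidecar_path",
]

SCHEMA_VERSION = "1.0"
FRAME_ORDER = "orientation-major,phase-minor"

_REQUIRED_PATTERN_FIELDS = (
    "orientation_deg",
    "period_nm",
    "modulation_depth",
    "mean_intensity",
    "initial_phase_rad",
    "phase_shifts_rad",
)


def default_sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def _pattern_record(p: SinusoidPattern) -> dict[str, Any]:
    return {
        "orientation_deg": p.orientation_deg,
        "period_nm": p.period_nm,
        "modulation_depth": p.modulation_depth,
        "mean_intensity": p.mean_intensity,
        "initial_phase_rad": p.initial_phase_rad,
        "phase_shifts_rad": list(p.phase_shifts_rad),
    }


def _pattern_from_record(rec: dict[str, Any], index: int) -> SinusoidPattern:
    missing = [f for f in _REQUIRED_PATTERN_FIELDS if f not in rec]
    if missing:
        raise MetadataError(f"pattern {index} missing fields: {', '.join(missing)}")
    return SinusoidPattern(
        mean_intensity=float(rec["mean_intensity"]),
        modulation_depth=float(rec["modulation_depth"]),
        period_nm=float(rec["period_nm"]),
        orientation_deg=float(rec["orientation_deg"]),
        initial_phase_rad=float(rec["initial_phase_rad"]),
        phase_shifts_rad=tuple(float(s) for s in rec["phase_shifts_rad"]),
    )


def stack_metadata(stack: SIMStack) -> dict[str, Any]:
    """The sidecar record for a stack (schema-versioned)."""
    noise = None
    if stack.noise is not None:
        noise = {
            "poisson_enabled": stack.noise.poisson_enabled,
            "read_noise_sd": stack.noise.read_noise_sd,
            "seed": stack.noise.seed,
            "note": "nominal camera-noise defaults; not calibrated to an instrument",
        }
    return {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "frame_order": FRAME_ORDER,
        "pixel_size_nm": stack.grid.pixel_size_nm,
        "psf_fwhm_nm": stack.psf.fwhm_nm,
        "patterns": [_pattern_record(p) for p in stack.patterns],
        "noise": noise,
        "scene_truth": stack.scene_truth,
    }


def write_stack(
    stack: SIMStack,
    tiff_path,
    sidecar_path=None,
    *,
    force: bool = False,
) -> tuple[Path, Path]:
    """Write a stack as a 9-page float32 TIFF plus JSON sidecar.

    Refuses to overwrite existing files unless ``force`` is set. Output is
    deterministic for identical inputs.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else default_sidecar_path(tiff_path)
    for path in (tiff_path, sidecar_path):
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    tifffile.imwrite(tiff_path, stack.frames.astype(np.float32))
    with open(sidecar_path, "w") as fh:
        json.dump(stack_metadata(stack), fh, indent=2, sort_keys=True)
    return tiff_path, sidecar_path


def read_stack(tiff_path, sidecar_path=None) -> SIMStack:
    """Read a 9-page TIFF stack and validate its sidecar against the schema.

    Frames are returned as float64 counts in the declared order.
    """
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else default_sidecar_path(tiff_path)
    frames = tifffile.imread(tiff_path).astype(float)
    if frames.ndim != 3 or frames.shape[0] != 9:
        raise ShapeError(
            f"{tiff_path} must hold 9 pages of equal shape, got array shape {frames.shape}"
        )
    if not sidecar_path.exists():
        raise MetadataError(f"metadata sidecar {sidecar_path} not found")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for fld in ("schema_version", "pixel_size_nm", "psf_fwhm_nm", "patterns", "frame_order"):
        if fld not in meta:
            raise MetadataError(f"sidecar missing field: {fld}")
    if meta["frame_order"] != FRAME_ORDER:
        raise MetadataError(f"unsupported frame_order: {meta['frame_order']!r}")
    if len(meta["patterns"]) != 3:
        raise MetadataError(f"expected 3 pattern records, got {len(meta['patterns'])}")
    patterns = tuple(_pattern_from_record(rec, i) for i, rec in enumerate(meta["patterns"]))
    for i, rec in enumerate(meta["patterns"]):
        if len(rec["phase_shifts_rad"]) != 3:
            raise MetadataError(f"pattern {i} must list 3 phase shifts")
    grid = Grid2D(frames.shape[1], frames.shape[2], float(meta["pixel_size_nm"]))
    noise = None
    if meta.get("noise") is not None:
        nrec = meta["noise"]
        noise = NoiseModel(
            poisson_enabled=bool(nrec.get("poisson_enabled", True)),
            read_noise_sd=float(nrec.get("read_noise_sd", 0.0)),
            seed=int(nrec.get("seed", 0)),
        )
    return SIMStack(
        frames=frames,
        patterns=patterns,  # type: ignore[arg-type]
        psf=GaussianPSF(float(meta["psf_fwhm_nm"])),
        grid=grid,
        noise=noise,
        scene_truth=meta.get("scene_truth"),
    )


def write_result(
    result,
    tiff_path,
    sidecar_path=None,
    *,
    force: bool = False,
) -> tuple[Path, Path]:
    """Write a reconstruction as single-page float32 TIFF + provenance JSON."""
    tiff_path = Path(tiff_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else default_sidecar_path(tiff_path)
    for path in (tiff_path, sidecar_path):
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    tifffile.imwrite(tiff_path, result.sr_image.astype(np.float32))
    provenance = {
        "schema_version": SCHEMA_VERSION,
        "software_version": __version__,
        "method": result.method,
        "pixel_size_nm": result.grid.pixel_size_nm,
        "shape": list(result.sr_image.shape),
        "psf_fwhm_nm": result.params.get("psf_fwhm_nm"),
        "wiener_w": result.params.get("wiener_w"),
        "noise_seed": result.params.get("noise_seed"),
        "pad_factor": result.params.get("pad_factor"),
        "patterns": [_pattern_record(p) for p in result.params.get("patterns", ())],
    }
    with open(sidecar_path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return tiff_path, sidecar_path
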