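"""Minimal preprocessing for fetal brain ultrasound volumes.

The pipeline contracts are deliberately small: resample to an isotropic
grid (0.6 mm by default), min–max intensity normalisation to [0, 1],
centre-crop to a fixed cube (160 voxels by default) around the brain
centroid, and restriction of structure labels to the distal hemisphere.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volume import BILATERAL, IntensityVolume, LabelVolume


class DegenerateInputError(ValueError):
    """Input volume lacks the structure the operation requires."""


def resample_isotropic(
    vol: LabelVolume | IntensityVolume, target_mm: float = 0.6
) -> LabelVolume | IntensityVolume:
    """Resample a volume to an isotropic voxel size.

    Intensity volumes are interpolated trilinearly; label volumes use
    nearest-neighbour so label identity is preserved.  Physical extent is
    preserved to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError("target voxel size must be positive")
    factors = tuple(s / target_mm for s in vol.spacing_mm)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return vol.copy()
    if isinstance(vol, LabelVolume):
        grid = ndimage.zoom(
            vol.grid, factors, order=0, mode="grid-constant", cval=0, grid_mode=True
        )
        out = vol.copy()
        out.grid = np.ascontiguousarray(grid)
        out.spacing_mm = (target_mm,) * 3
        return out
    grid = ndimage.zoom(
        vol.grid, factors, order=1, mode="grid-constant", cval=0.0, grid_mode=True
    )
    return IntensityVolume(grid, (target_mm,) * 3)


def minmax_normalize(vol: IntensityVolume) -> IntensityVolume:
    """Affinely map intensities onto [0, 1] (min→0, max→1)."""
    lo = float(vol.grid.min())
    hi = float(vol.grid.max())
    if hi <= lo:
        raise DegenerateInputError("constant intensity volume cannot be normalised")
    return IntensityVolume((vol.grid - lo) / (hi - lo), vol.spacing_mm)


def _foreground_centroid(grid: np.ndarray) -> np.ndarray:
    coords = np.argwhere(grid > 0)
    if coords.size == 0:
        raise DegenerateInputError("empty foreground: cannot locate the brain centre")
    return coords.mean(axis=0)


def crop_center(
    vol: LabelVolume | IntensityVolume, size: int = 160
) -> LabelVolume | IntensityVolume:
    """Crop (or pad) to ``size³`` voxels centred on the foreground centroid."""
    if size <= 0:
        raise ValueError("crop size must be positive")
    centroid = _foreground_centroid(vol.grid)
    out = np.zeros((size,) * 3, dtype=vol.grid.dtype)
    starts = [int(round(c)) - size // 2 for c in centroid]
    src, dst = [], []
    for ax, s in enumerate(starts):
        lo = max(s, 0)
        hi = min(s + size, vol.grid.shape[ax])
        if hi <= lo:
            raise DegenerateInputError("crop window does not intersect the volume")
        src.append(slice(lo, hi))
        dst.append(slice(lo - s, hi - s))
    out[tuple(dst)] = vol.grid[tuple(src)]
    if isinstance(vol, LabelVolume):
        res = vol.copy()
        res.grid = out
        return res
    return IntensityVolume(out, vol.spacing_mm)


def _left_right_axis(tb_mask: np.ndarray) -> int:
    """Grid axis of greatest extent of the TB mask (left–right by convention)."""
    coords = np.argwhere(tb_mask)
    extents = coords.max(axis=0) - coords.min(axis=0)
    return int(np.argmax(extents))


def restrict_to_distal(vol: LabelVolume, distal: str) -> LabelVolume:
    """Zero structure labels on the proximal hemisphere.

    TB and CSP are retained bilaterally; every other structure label on the
    proximal side is replaced by the generic TB label (the tissue is still
    brain, but acoustic shadowing precludes structure-level labelling).
    The mid-sagittal plane passes through the TB centroid orthogonal to the
    axis of greatest left–right extent; higher voxel indices along that
    axis are taken as the right side.
    """
    if distal not in ("left", "right"):
        raise ValueError("distal hemisphere must be 'left' or 'right'")
    if vol.hemisphere != "both":
        return vol.copy()
    tb = vol.mask("TB")
    if not tb.any():
        raise DegenerateInputError("empty TB mask: mid-sagittal plane underivable")
    axis = _left_right_axis(tb)
    centroid = _foreground_centroid(vol.grid)
    split = centroid[axis]
    idx = np.arange(vol.grid.shape[axis])
    proximal_side = idx < split if distal == "right" else idx >= split
    sel = [slice(None)] * 3
    sel[axis] = proximal_side
    out = vol.copy()
    keep = np.isin(
        out.grid[tuple(sel)], [0] + [out.label_map[n] for n in BILATERAL]
    )
    region = out.grid[tuple(sel)]
    region[~keep] = out.label_map["TB"]
    out.grid[tuple(sel)] = region
    out.hemisphere = distal
    return out
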