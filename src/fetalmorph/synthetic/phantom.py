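"""Nested-sphere 3D label phantoms.

The phantom is a sphere-based idealisation of a segmented fetal brain
scan: a total-brain (TB) ball whose volume tracks the published normative
total-brain-volume growth equation at the requested gestational age, an
outer cortical-plate (CoP) shell partitioned into five lobes by angular
sectors about the left–right axis, a white-matter (WM) interior, and
subcortical structures as interior balls sized by configurable fractions
of total brain volume.  There is no gyrification: every downstream
geometric measure (volume, surface area, depth, thickness) then has an
analytic oracle on spheres and shells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..growth import TBV_REFERENCE_MODEL, FPGrowthModel
from ..volume import DEFAULT_LABELS, LOBES, LabelVolume

#: Default subcortical structure volumes as fractions of total brain volume.
#: Mid-gestation plausible constants; configurable per spec.
DEFAULT_STRUCTURE_FRACTIONS: dict[str, float] = {
    "DGM": 0.035,
    "CB": 0.025,
    "Th": 0.012,
    "BS": 0.010,
    "LV": 0.007,
    "ChP": 0.005,
    "FH": 0.005,
    "CSP": 0.002,
}

#: Unit placement directions (grid-axis order: x = left–right, y, z).
#: CSP sits at the centre so it straddles the mid-sagittal plane.
_PLACEMENT: dict[str, tuple[float, float, float]] = {
    "DGM": (0.0, 1.0, 0.0),
    "CB": (0.0, -1.0, 0.0),
    "Th": (0.0, 0.0, 1.0),
    "BS": (0.0, 0.0, -1.0),
    "LV": (1.0, 0.0, 0.0),
    "FH": (-1.0, 0.0, 0.0),
    "ChP": (0.57735, 0.57735, 0.57735),
    "CSP": (0.0, 0.0, 0.0),
}

_TWO_PI = 2.0 * math.pi


def default_lobe_sectors() -> dict[str, tuple[float, float]]:
    """Five equal angular sectors partitioning [0, 2π)."""
    width = _TWO_PI / 5.0
    return {lobe: (i * width, (i + 1) * width) for i, lobe in enumerate(LOBES)}


class GeometryError(ValueError):
    """Requested geometry does not fit the voxel grid."""


@dataclass
class PhantomSpec:
    """Specification of a synthetic label phantom."""

    ga_weeks: float
    spacing_mm: float = 0.6
    grid_size: int = 160
    structure_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_FRACTIONS)
    )
    lobe_sector_angles: dict[str, tuple[float, float]] = field(
        default_factory=default_lobe_sectors
    )
    cop_thickness_mm: float = 2.5
    mean_curve: FPGrowthModel = field(default_factory=lambda: TBV_REFERENCE_MODEL)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mean_curve.ga_domain
        if not lo <= self.ga_weeks <= hi:
            raise ValueError(f"ga_weeks must lie in [{lo}, {hi}]")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.grid_size <= 0:
            raise ValueError("grid size must be positive")
        for name, f in self.structure_fractions.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"structure fraction for {name} must be in (0,1)")
        self._validate_sectors()

    def _validate_sectors(self) -> None:
        sectors = sorted(self.lobe_sector_angles.values())
        if not sectors:
            raise ValueError("at least one lobe sector required")
        cover = 0.0
        for lo, hi in sectors:
            if hi <= lo:
                raise ValueError("lobe sector end must exceed its start")
            if lo < cover - 1e-9:
                raise ValueError("lobe sectors overlap")
            cover = hi
        if abs(sectors[0][0]) > 1e-9 or abs(cover - _TWO_PI) > 1e-9:
            raise ValueError("lobe sectors must partition [0, 2π)")

    @property
    def tbv_mm3(self) -> float:
        """Target total brain volume in mm³ (reference curve is in cm³)."""
        return float(np.asarray(self.mean_curve.mean(self.ga_weeks)).item()) * 1000.0

    @property
    def radius_mm(self) -> float:
        return (3.0 * self.tbv_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def generate_phantom(spec: PhantomSpec) -> LabelVolume:
    """Generate the nested-label phantom for *spec*.

    Raises :class:`GeometryError` when the implied brain radius does not
    fit the grid with a one-voxel margin.
    """
    n = spec.grid_size
    a = spec.spacing_mm
    R = spec.radius_mm
    half_extent = (n - 1) / 2.0 * a
    if R + a > half_extent:
        raise GeometryError(
            f"brain radius {R:.1f} mm exceeds grid half-extent {half_extent:.1f} mm"
        )
    centre = (n - 1) / 2.0
    coords = (np.arange(n) - centre) * a
    dx = coords[:, None, None]
    dy = coords[None, :, None]
    dz = coords[None, None, :]
    r = np.sqrt(dx**2 + dy**2 + dz**2)

    labels = DEFAULT_LABELS
    grid = np.zeros((n, n, n), dtype=np.int16)

    interior = r <= R - spec.cop_thickness_mm
    shell = (r <= R) & ~interior
    grid[interior] = labels["WM"]

    theta = np.mod(np.arctan2(dz + 0.0 * dx, dy + 0.0 * dx), _TWO_PI)
    for lobe, (lo, hi) in spec.lobe_sector_angles.items():
        sector = shell & (theta >= lo) & (theta < hi)
        grid[sector] = labels[lobe]
    # numerical wrap-around at 2π: assign any stragglers to the first sector
    first = min(spec.lobe_sector_angles, key=lambda k: spec.lobe_sector_angles[k][0])
    grid[shell & (grid == 0)] = labels[first]

    margin = max(a, 1.0)
    inner_r = R - spec.cop_thickness_mm - margin
    for name, frac in spec.structure_fractions.items():
        rs = frac ** (1.0 / 3.0) * R
        direction = np.asarray(_PLACEMENT.get(name, (0.0, 1.0, 0.0)))
        d = max(inner_r - rs, 0.0) * (np.linalg.norm(direction) > 0)
        cx, cy, cz = direction * d if np.linalg.norm(direction) > 0 else (0.0, 0.0, 0.0)
        ball = np.sqrt((dx - cx) ** 2 + (dy - cy) ** 2 + (dz - cz) ** 2) <= rs
        # carve from WM only, preserving label exclusivity
        grid[ball & (grid == labels["WM"])] = labels[name]

    return LabelVolume(grid, (a, a, a), label_map=dict(labels), hemisphere="both")
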