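"""In-memory containers for 3D label and intensity volumes.

A :class:`LabelVolume` is a single integer grid over an isotropic (or
anisotropic) voxel lattice together with a name→integer label dictionary.
Eleven anatomical structures plus five cortical lobes are recognised by
default.  The five lobes partition the cortical-plate (CoP) shell, so a
voxel never carries both a lobe label and the CoP label: the CoP mask is
derived as the union of the explicit CoP label and the lobe labels, and the
total-brain (TB) mask as the union of all foreground labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Default label dictionary: 11 regions of interest + 5 cortical lobes.
#: TB is generic brain tissue (used e.g. for the proximal hemisphere after
#: distal restriction, where structure labels are not available).
DEFAULT_LABELS: dict[str, int] = {
    "TB": 1,
    "CoP": 2,
    "WM": 3,
    "DGM": 4,
    "CB": 5,
    "Th": 6,
    "LV": 7,
    "ChP": 8,
    "FH": 9,
    "BS": 10,
    "CSP": 11,
    "FL": 12,
    "TL": 13,
    "PL": 14,
    "OL": 15,
    "IL": 16,
}

#: Names of the five cortical-lobe parcellations.
LOBES = ("FL", "TL", "PL", "OL", "IL")

#: Structures measured on both hemispheres; all others are restricted to
#: the distal (probe-far, shadow-free) hemisphere.
BILATERAL = ("TB", "CSP")


class UnknownLabelError(ValueError):
    """Grid contains integer values absent from the label dictionary."""


@dataclass
class LabelVolume:
    """Integer label grid with physical spacing.

    Parameters
    ----------
    grid
        3D integer array; 0 is background.
    spacing_mm
        Per-axis voxel edge length in mm.
    label_map
        Mapping from structure name to integer label value.
    hemisphere
        Which cerebral hemisphere the structure labels cover:
        ``"left"``, ``"right"`` or ``"both"``.
    """

    grid: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)
    label_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABELS))
    hemisphere: str = "both"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must have an integer dtype")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.hemisphere not in ("left", "right", "both"):
            raise ValueError(f"invalid hemisphere {self.hemisphere!r}")
        self.validate_labels()

    def validate_labels(self) -> None:
        present = set(np.unique(self.grid).tolist()) - {0}
        known = set(self.label_map.values())
        unknown = sorted(present - known)
        if unknown:
            raise UnknownLabelError(
                f"grid contains values not in the label dictionary: {unknown}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask for a named structure.

        ``TB`` is the union of all foreground voxels and ``CoP`` the union
        of the CoP label and the five lobe labels (the lobes partition the
        cortical-plate shell when present).
        """
        if name == "TB":
            return self.grid > 0
        if name == "CoP":
            values = [self.label_map["CoP"]] + [
                self.label_map[l] for l in LOBES if l in self.label_map
            ]
            return np.isin(self.grid, values)
        if name not in self.label_map:
            raise KeyError(f"unknown structure {name!r}")
        return self.grid == self.label_map[name]

    def copy(self) -> "LabelVolume":
        return replace(self, grid=self.grid.copy(), label_map=dict(self.label_map))


@dataclass
class IntensityVolume:
    """Scalar intensity grid with physical spacing."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.6, 0.6, 0.6)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("intensity grid must be 3D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("intensity grid contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.grid.copy(), self.spacing_mm)
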