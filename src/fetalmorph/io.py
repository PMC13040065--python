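"""NIfTI-1 reading and writing for label and intensity volumes.

Label volumes round-trip bit-exactly (integer dtype preserved); voxel
spacing travels in the NIfTI header zooms.  No affine rotations are in
scope: volumes are written with a diagonal affine of the voxel spacing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import DEFAULT_LABELS, IntensityVolume, LabelVolume


def write_volume(vol: LabelVolume | IntensityVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (.nii or .nii.gz)."""
    if isinstance(vol, LabelVolume):
        data = np.asarray(vol.grid, dtype=np.int16)
    else:
        data = np.asarray(vol.grid, dtype=np.float32)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def read_volume(
    path: str | Path,
    kind: str = "label",
    label_map: dict[str, int] | None = None,
    hemisphere: str = "both",
) -> LabelVolume | IntensityVolume:
    """Read a NIfTI volume.

    Parameters
    ----------
    kind
        ``"label"`` (validated against *label_map*) or ``"intensity"``.
    label_map
        Label dictionary for label volumes; defaults to the shipped one.
    """
    img = nib.load(str(path))
    # zooms are stored as float32; round off the representation noise
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    data = np.asanyarray(img.dataobj)
    if kind == "intensity":
        return IntensityVolume(np.asarray(data, dtype=np.float64), spacing)
    if kind != "label":
        raise ValueError(f"unknown volume kind {kind!r}")
    grid = np.asarray(np.rint(data), dtype=np.int32)
    return LabelVolume(
        grid,
        spacing,
        label_map=dict(label_map or DEFAULT_LABELS),
        hemisphere=hemisphere,
    )


def write_label_dictionary(path: str | Path, label_map: dict[str, int] | None = None) -> None:
    """Write the name→integer label dictionary as JSON."""
    Path(path).write_text(json.dumps(label_map or DEFAULT_LABELS, indent=2) + "\n")


def read_label_dictionary(path: str | Path) -> dict[str, int]:
    return {str(k): int(v) for k, v in json.loads(Path(path).read_text()).items()}
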