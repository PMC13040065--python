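"""Extraction of the 28 image-derived phenotypes (IDPs) from a label volume.

Measures
--------
- structure volumes: voxel count × voxel volume (mm³);
- cortical-plate surface area: Lewiner marching-cubes mesh, summed
  triangle areas (mm²);
- cortical depth: Euclidean distance transform of the total-brain mask
  (distance in mm from each voxel to the nearest background voxel),
  sampled over the cortical plate;
- cortical thickness: from each pial-boundary voxel, a ray is marched
  inward along the interpolated gradient of the depth field until it
  enters white matter; the path length is the local thickness (mm);
- Sylvian fissure depth: median cortical depth over the insular lobe;
- lobe summaries: volume and mean depth/thickness per cortical lobe;
- relative volumes: structure/TBV and lobe/CoPV ratios, including the
  insular-to-parietal ratio rILV/rPLV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import marching_cubes

from .volume import LOBES, LabelVolume

logger = logging.getLogger(__name__)

#: The 28 IDP names in canonical order.
IDP_NAMES: tuple[str, ...] = (
    "TBV", "CoPV", "WMV", "DGMV", "CBV", "ThV", "LVV", "ChPV", "FHV",
    "BSV", "CSPV", "CoPSA", "SFD",
    "FLV", "TLV", "PLV", "OLV", "ILV",
    "FLD", "TLD", "PLD", "OLD", "ILD",
    "FLT", "TLT", "PLT", "OLT", "ILT",
)

_VOLUME_STRUCTURES = (
    ("TBV", "TB"), ("CoPV", "CoP"), ("WMV", "WM"), ("DGMV", "DGM"),
    ("CBV", "CB"), ("ThV", "Th"), ("LVV", "LV"), ("ChPV", "ChP"),
    ("FHV", "FH"), ("BSV", "BS"), ("CSPV", "CSP"),
)


class ContainmentError(ValueError):
    """A mask is not contained where the operation requires."""


@dataclass
class SurfaceMesh:
    """Triangular surface mesh with vertices in mm."""

    vertices: np.ndarray
    faces: np.ndarray


@dataclass
class DepthMap:
    """Per-voxel scalar field (mm) defined over a mask."""

    values: np.ndarray
    mask: np.ndarray
    mask_label: str = ""

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]


def structure_volume(vol: LabelVolume, structure: str) -> float:
    """Volume of a named structure in mm³ (voxel count × voxel volume)."""
    mask = vol.mask(structure)  # raises KeyError for unknown names
    return float(mask.sum()) * vol.voxel_volume_mm3


def extract_surface(
    mask: np.ndarray, spacing_mm=(0.6, 0.6, 0.6), smooth_sigma: float = 1.0
) -> SurfaceMesh:
    """Closed triangular mesh of a binary mask at iso-level 0.5.

    The mask is zero-padded by one voxel so surfaces touching the grid
    border still close; the Lewiner topology-consistent marching-cubes
    variant is used.  A light Gaussian pre-smoothing (*smooth_sigma*
    voxels; 0 disables it) anti-aliases the binary mask — meshing the raw
    mask carries a persistent staircase area bias of roughly +9% on
    curved surfaces.  Vertices are returned in mm.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot mesh an empty mask")
    pad = 1 + int(np.ceil(3 * smooth_sigma))
    padded = np.pad(mask, pad).astype(np.float64)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, sigma=smooth_sigma)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=tuple(spacing_mm), method="lewiner"
    )
    verts = verts - pad * np.asarray(spacing_mm)  # undo the pad offset
    return SurfaceMesh(vertices=verts, faces=faces)


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total mesh area (mm²): sum of triangle areas; degenerate faces add 0."""
    v = mesh.vertices[mesh.faces]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    n_degenerate = int(np.sum(areas == 0.0))
    if n_degenerate:
        logger.info("mesh has %d degenerate faces (zero area)", n_degenerate)
    return float(areas.sum())


def distance_transform(tb_mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Exact Euclidean distance (mm) from each voxel to the nearest background."""
    tb_mask = np.asarray(tb_mask, dtype=bool)
    if tb_mask.all():
        raise ValueError("mask fills the grid: depth is unbounded")
    return ndimage.distance_transform_edt(tb_mask, sampling=spacing_mm)


def depth_map(
    tb_mask: np.ndarray, target_mask: np.ndarray, spacing_mm=(0.6, 0.6, 0.6)
) -> DepthMap:
    """Cortical depth: distance transform of the brain mask over *target_mask*."""
    tb_mask = np.asarray(tb_mask, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    if np.any(target_mask & ~tb_mask):
        raise ContainmentError("target mask is not contained in the TB mask")
    dist = distance_transform(tb_mask, spacing_mm)
    return DepthMap(values=dist * target_mask, mask=target_mask)


def thickness_map(
    cop_mask: np.ndarray,
    wm_mask: np.ndarray,
    tb_mask: np.ndarray | None = None,
    spacing_mm=(0.6, 0.6, 0.6),
    step_voxels: float = 0.25,
    cap_mm: float = 10.0,
) -> DepthMap:
    """Voxel-wise cortical thickness by gradient ray-marching.

    From every pial-boundary voxel (cortical-plate voxel 6-adjacent to
    background) a ray is marched inward along the trilinearly interpolated
    gradient of the depth field, in steps of *step_voxels*, until it
    enters white matter; the traversed path length is the thickness at
    that voxel.  Rays are capped at *cap_mm* to contain degenerate
    geometry.  Values are recorded at the seed voxels.
    """
    cop_mask = np.asarray(cop_mask, dtype=bool)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not cop_mask.any():
        raise ValueError("empty cortical-plate mask")
    if np.any(cop_mask & wm_mask):
        raise ContainmentError("cortical-plate and white-matter masks overlap")
    # WM must back the cortical plate somewhere
    dilated = ndimage.binary_dilation(cop_mask)
    if not np.any(dilated & wm_mask):
        raise ContainmentError("white matter is nowhere adjacent to the cortex")

    if tb_mask is None:
        tb_mask = cop_mask | wm_mask
    spacing = np.asarray(spacing_mm, dtype=np.float64)
    depth = distance_transform(tb_mask, spacing)

    exterior = ~np.asarray(tb_mask, dtype=bool)
    near_bg = ndimage.binary_dilation(
        exterior, structure=ndimage.generate_binary_structure(3, 1)
    )
    seeds = np.argwhere(cop_mask & near_bg)
    if seeds.size == 0:
        # cortex nowhere touches background (e.g. fully interior shell)
        seeds = np.argwhere(cop_mask)

    grad = np.stack(np.gradient(depth, *spacing), axis=0)
    wm_f = wm_mask.astype(np.float64)

    pos = seeds.astype(np.float64)
    n = len(pos)
    lengths = np.zeros(n)
    result = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    step_mm = float(step_voxels) * float(np.min(spacing))
    max_steps = int(np.ceil(cap_mm / step_mm)) + 1

    for _ in range(max_steps):
        if not active.any():
            break
        idx = pos[active].T  # voxel-index coordinates
        g = np.stack(
            [ndimage.map_coordinates(grad[k], idx, order=1, mode="nearest")
             for k in range(3)],
            axis=1,
        )
        norms = np.linalg.norm(g, axis=1)
        dead = norms < 1e-9
        direction = np.zeros_like(g)
        direction[~dead] = g[~dead] / norms[~dead, None]
        # advance by a fixed physical step along the inward gradient
        pos[active] += direction * (step_mm / spacing)[None, :]
        lengths[active] += step_mm
        in_wm = ndimage.map_coordinates(wm_f, pos[active].T, order=1, mode="nearest") >= 0.5
        finished = in_wm | dead | (lengths[active] >= cap_mm)
        act_idx = np.flatnonzero(active)
        result[act_idx[finished]] = np.minimum(lengths[act_idx[finished]], cap_mm)
        active[act_idx[finished]] = False
    result[np.isnan(result)] = cap_mm
    # seed voxel centres sit half a voxel below the pial surface
    result = np.minimum(result + 0.5 * float(np.min(spacing)), cap_mm)

    values = np.zeros_like(depth)
    mask = np.zeros_like(cop_mask)
    values[tuple(seeds.T)] = result
    mask[tuple(seeds.T)] = True
    return DepthMap(values=values, mask=mask, mask_label="CoP")


def lobe_summary(
    lobe_mask: np.ndarray,
    depth: DepthMap | None = None,
    thickness: DepthMap | None = None,
    spacing_mm=(0.6, 0.6, 0.6),
) -> dict[str, float]:
    """Volume (mm³) and mean depth/thickness (mm) over a lobe mask.

    Empty lobes yield NaN summaries (missing, not zero).
    """
    lobe_mask = np.asarray(lobe_mask, dtype=bool)
    out: dict[str, float] = {}
    if not lobe_mask.any():
        return {"volume": np.nan, "mean_depth": np.nan, "mean_thickness": np.nan}
    out["volume"] = float(lobe_mask.sum()) * float(np.prod(spacing_mm))
    for key, dmap in (("mean_depth", depth), ("mean_thickness", thickness)):
        if dmap is None:
            out[key] = np.nan
            continue
        sel = lobe_mask & dmap.mask
        out[key] = float(dmap.values[sel].mean()) if sel.any() else np.nan
    return out


def sylvian_fissure_depth(depth: DepthMap, insula_mask: np.ndarray) -> float:
    """Median cortical depth over the insula (robust to boundary extremes)."""
    insula_mask = np.asarray(insula_mask, dtype=bool)
    sel = insula_mask & depth.mask
    if not sel.any():
        return float("nan")
    return float(np.median(depth.values[sel]))


@dataclass
class IDPRecord:
    """One scan's 28 measures plus metadata."""

    measures: dict[str, float]
    fetus_id: str = ""
    site: str = ""
    sex: str = ""
    ga_weeks: float = float("nan")
    hemisphere: str = ""

    def to_row(self) -> dict:
        row = {
            "fetus_id": self.fetus_id,
            "site": self.site,
            "sex": self.sex,
            "ga_weeks": self.ga_weeks,
            "hemisphere": self.hemisphere,
        }
        row.update({k: self.measures.get(k, np.nan) for k in IDP_NAMES})
        return row


def extract_all_idps(vol: LabelVolume, meta: dict | None = None) -> IDPRecord:
    """Compute all 28 IDPs from a preprocessed label volume.

    Structures whose labels are absent yield NaN for their measures
    rather than failing the whole extraction.
    """
    meta = meta or {}
    spacing = vol.spacing_mm
    measures: dict[str, float] = {}

    for idp, structure in _VOLUME_STRUCTURES:
        try:
            measures[idp] = structure_volume(vol, structure)
        except KeyError:
            measures[idp] = np.nan

    tb = vol.mask("TB")
    cop = vol.mask("CoP")
    wm = vol.mask("WM")

    if cop.any():
        try:
            mesh = extract_surface(cop, spacing)
            measures["CoPSA"] = mesh_surface_area(mesh)
        except ValueError:
            measures["CoPSA"] = np.nan
        depth = depth_map(tb, cop, spacing)
        try:
            thickness = thickness_map(cop, wm, tb_mask=tb, spacing_mm=spacing)
        except (ValueError, ContainmentError):
            thickness = None
    else:
        depth = None
        thickness = None
        measures["CoPSA"] = np.nan

    for lobe in LOBES:
        try:
            lobe_mask = vol.mask(lobe)
        except KeyError:
            lobe_mask = np.zeros_like(vol.grid, dtype=bool)
        summary = lobe_summary(lobe_mask, depth, thickness, spacing)
        measures[f"{lobe}V"] = summary["volume"]
        measures[f"{lobe}D"] = summary["mean_depth"]
        measures[f"{lobe}T"] = summary["mean_thickness"]

    if depth is not None:
        try:
            insula = vol.mask("IL")
        except KeyError:
            insula = np.zeros_like(vol.grid, dtype=bool)
        measures["SFD"] = sylvian_fissure_depth(depth, insula)
    else:
        measures["SFD"] = np.nan

    return IDPRecord(
        measures=measures,
        fetus_id=str(meta.get("fetus_id", "")),
        site=str(meta.get("site", "")),
        sex=str(meta.get("sex", "")),
        ga_weeks=float(meta.get("ga_weeks", np.nan)),
        hemisphere=str(meta.get("hemisphere", vol.hemisphere)),
    )


@dataclass
class RelativeIDPs:
    """Structure/TBV and lobe/CoPV ratios plus the insular:parietal ratio."""

    structure_over_tbv: dict[str, float]
    lobe_over_copv: dict[str, float]
    rilv_over_rplv: float


def relative_volumes(rec: IDPRecord) -> RelativeIDPs:
    """Relative volumes; rILV/rPLV is NaN when the parietal lobe is empty."""
    tbv = rec.measures.get("TBV", np.nan)
    copv = rec.measures.get("CoPV", np.nan)
    if not tbv > 0:
        raise ValueError("TBV must be positive to form relative volumes")
    if not copv > 0:
        raise ValueError("CoPV must be positive to form relative volumes")
    structure = {
        idp: rec.measures.get(idp, np.nan) / tbv
        for idp, _ in _VOLUME_STRUCTURES
        if idp != "TBV"
    }
    lobe = {f"r{l}V": rec.measures.get(f"{l}V", np.nan) / copv for l in LOBES}
    rplv = lobe["rPLV"]
    rilv = lobe["rILV"]
    ratio = rilv / rplv if rplv and rplv > 0 else float("nan")
    return RelativeIDPs(
        structure_over_tbv=structure, lobe_over_copv=lobe, rilv_over_rplv=ratio
    )


def records_to_table(records: list[IDPRecord]) -> pd.DataFrame:
    """Stack IDP records into one row-per-scan table."""
    return pd.DataFrame([r.to_row() for r in records])
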