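"""From lethal-dose mask to the thermometry-predicted lesion.

Mirrors the reading-room workflow: threshold the dose map, select the
main dose island around the antenna, clip anything reaching beyond the
liver, then add back the needle signal void that the lesion
encapsulates (no temperature - hence no dose - can be measured inside
the void).  The island selection and liver comparison, manual in the
clinical workflow, are automated here via the antenna seed voxel and a
provided liver mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, UsageError
from .geometry import AcquisitionGeometry

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise UsageError("3D connectivity must be one of 6, 18, 26")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


@dataclass
class IslandSelection:
    mask: np.ndarray
    label: int | None
    status: str


@dataclass
class LesionSegment:
    """Final lesion mask with volume and provenance counters."""

    mask: np.ndarray
    island_label: int | None
    seed_voxel: tuple[int, int, int]
    volume_mm3: float
    status: str
    removed_by_liver_clip: int = 0
    added_by_void_fill: int = 0


def select_main_island(
    lethal: np.ndarray,
    seed_voxel,
    geometry: AcquisitionGeometry,
    connectivity: int = 26,
    search_radius_mm: float = 10.0,
) -> IslandSelection:
    """Connected component of the lethal mask containing (or nearest) the seed.

    If the seed voxel itself is unlabeled - typically because it sits in
    the needle signal void - the component with the closest labeled
    voxel within ``search_radius_mm`` is chosen; ties go to the larger
    component, then the lowest label.  An empty result carries an
    explicit status instead of raising, mirroring lesions excluded for
    insufficient thermal signal.
    """
    lethal = np.asarray(lethal, dtype=bool)
    seed = tuple(int(i) for i in seed_voxel)
    if any(i < 0 or i >= n for i, n in zip(seed, lethal.shape)):
        raise DomainError(f"seed voxel {seed} outside field of view {lethal.shape}")
    empty = np.zeros_like(lethal)
    if not lethal.any():
        return IslandSelection(empty, None, "no lethal dose detected")
    labels, _ = ndimage.label(lethal, structure=_structure(connectivity))
    seed_label = labels[seed]
    if seed_label == 0:
        coords = np.argwhere(lethal)
        spacing = np.asarray(geometry.voxel_size_mm)
        d = np.linalg.norm((coords - np.asarray(seed)) * spacing, axis=1)
        dmin = d.min()
        if dmin > search_radius_mm:
            return IslandSelection(
                empty, None,
                f"no lethal-dose component within {search_radius_mm} mm of the seed",
            )
        near = coords[d <= dmin + 1e-9]
        candidates = sorted(
            {int(labels[tuple(v)]) for v in near},
            key=lambda lab: (-int((labels == lab).sum()), lab),
        )
        seed_label = candidates[0]
    return IslandSelection(labels == seed_label, int(seed_label), "ok")


def clip_to_liver(mask: np.ndarray, liver_mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Voxelwise AND with the liver; returns (clipped mask, removed count)."""
    mask = np.asarray(mask, dtype=bool)
    liver_mask = np.asarray(liver_mask, dtype=bool)
    if mask.shape != liver_mask.shape:
        raise UsageError("lesion and liver masks must share the same grid")
    if not liver_mask.any():
        raise UsageError("liver mask is empty")
    clipped = mask & liver_mask
    return clipped, int(mask.sum() - clipped.sum())


def _fill_2d_along(mask: np.ndarray, axis: int) -> np.ndarray:
    out = np.zeros_like(mask)
    for i in range(mask.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = i
        out[tuple(sl)] = ndimage.binary_fill_holes(mask[tuple(sl)])
    return out


def enclosed_by_hull(mask: np.ndarray) -> np.ndarray:
    """Voxels enclosed by the mask's filled hull.

    A voxel counts as enclosed if it lies in a cavity fully surrounded
    in 3D, or is surrounded by the mask in some axis-aligned
    cross-sectional plane (which captures a needle tunnel that opens to
    the volume edge along its own axis but is ringed by dose radially).
    """
    mask = np.asarray(mask, dtype=bool)
    fill3d = ndimage.binary_fill_holes(mask)
    enclosed = fill3d.copy()
    for axis in range(3):
        enclosed |= _fill_2d_along(mask, axis)
    return enclosed


def fill_needle_void(
    mask: np.ndarray, needle_mask: np.ndarray | None
) -> tuple[np.ndarray, int]:
    """Fill enclosed cavities and add the encapsulated part of the needle void.

    Needle voxels outside the dose hull (e.g. the shaft running back to
    the body wall) are NOT added - only the portion the lesion
    encapsulates belongs to the predicted lesion.  Returns
    (filled mask, voxels added).
    """
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    if needle_mask is not None:
        needle_mask = np.asarray(needle_mask, dtype=bool)
        if needle_mask.shape != mask.shape:
            raise UsageError("needle mask must share the lesion mask grid")
        filled = filled | (needle_mask & enclosed_by_hull(mask))
    return filled, int(filled.sum() - mask.sum())


def mask_volume(mask: np.ndarray, geometry: AcquisitionGeometry) -> float:
    """Voxel-count volume in mm^3."""
    return float(np.asarray(mask, dtype=bool).sum()) * geometry.voxel_volume_mm3


def segment_lesion(
    lethal: np.ndarray,
    seed_voxel,
    liver_mask: np.ndarray,
    geometry: AcquisitionGeometry,
    needle_mask: np.ndarray | None = None,
    connectivity: int = 26,
    search_radius_mm: float = 10.0,
    fill_void: bool = True,
    island_label: int | None = None,
) -> LesionSegment:
    """Full segmentation chain: island select -> liver clip -> void fill.

    The stage order is part of the contract (clipping before filling);
    ``island_label`` overrides the seeded selection to reproduce a
    manual island choice.
    """
    if island_label is not None:
        labels, _ = ndimage.label(
            np.asarray(lethal, bool), structure=_structure(connectivity)
        )
        sel = IslandSelection(labels == island_label, island_label, "ok")
        if not sel.mask.any():
            sel = IslandSelection(sel.mask, None, f"island label {island_label} not found")
    else:
        sel = select_main_island(lethal, seed_voxel, geometry, connectivity,
                                 search_radius_mm)
    if not sel.mask.any():
        return LesionSegment(
            sel.mask, sel.label, tuple(int(i) for i in seed_voxel),
            0.0, sel.status,
        )
    clipped, removed = clip_to_liver(sel.mask, liver_mask)
    if fill_void:
        final, added = fill_needle_void(clipped, needle_mask)
    else:
        final, added = clipped, 0
    return LesionSegment(
        final, sel.label, tuple(int(i) for i in seed_voxel),
        mask_volume(final, geometry), sel.status,
        removed_by_liver_clip=removed, added_by_void_fill=added,
    )
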