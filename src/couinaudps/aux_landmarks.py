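"""Auxiliary landmark extraction from organ label masks.

Nine auxiliary landmarks are derived from organ segmentations (as produced
by any whole-body segmenter) with three deterministic geometric rules:

* ``extreme_point`` — centroid of the farthest slab of voxels along a
  signed world axis (a robust "top of organ" point);
* ``corner_point`` — the voxel maximising the sum of two normalised signed
  coordinates (a bounding-box-normalised corner);
* ``centroid`` — the mask's voxel centroid.

"Left"/"right" in landmark names follow radiological display convention
(image left = patient right); the axis table below encodes that explicitly
under the package's RAS world axes (+x Right, +y Anterior, +z Superior).
Absent structures simply yield not-present landmarks, mirroring the
missing-landmark handling elsewhere in the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .landmarks import N_LANDMARKS, LandmarkSet, landmark_index
from .volumes import LabelVolume

logger = logging.getLogger(__name__)

#: Default robust slab fraction for extreme points; resists single-voxel
#: segmentation noise.
DEFAULT_ROBUST_FRACTION = 0.05

_AXES = {"+x": (0, +1), "-x": (0, -1), "+y": (1, +1), "-y": (1, -1),
         "+z": (2, +1), "-z": (2, -1)}


@dataclass(frozen=True)
class HeuristicSpec:
    """Rule binding one auxiliary landmark to a source structure."""

    landmark: str
    source_structure: str
    rule: str                 # extreme_point | corner_point | centroid
    axes: tuple[str, ...]     # one signed axis (extreme) or two (corner)
    robust_fraction: float = DEFAULT_ROBUST_FRACTION


#: Default heuristic table; overridable by passing a custom table to
#: :func:`extract_auxiliary_landmarks`.
DEFAULT_HEURISTICS: tuple[HeuristicSpec, ...] = (
    HeuristicSpec("GB_TOP", "gallbladder", "extreme_point", ("+z",)),
    HeuristicSpec("HEART_BR", "heart", "corner_point", ("-x", "-z")),
    HeuristicSpec("LIVER_BR", "liver", "corner_point", ("-x", "-z")),
    HeuristicSpec("LIVER_CENTER", "liver", "centroid", ()),
    HeuristicSpec("LIVER_LC", "liver", "corner_point", ("+x", "-z")),
    HeuristicSpec("PANC_TR", "pancreas", "corner_point", ("-x", "+z")),
    HeuristicSpec("RKID_TOP", "right kidney", "extreme_point", ("+z",)),
    HeuristicSpec("PV_TOP", "portal vein", "extreme_point", ("+z",)),
    HeuristicSpec("LIVER_TR", "liver", "corner_point", ("-x", "+z")),
)


def _structure_world_coords(masks: LabelVolume, structure: str) -> np.ndarray | None:
    """World coordinates (M, 3) of a structure's voxels, or None if absent.

    Voxels are enumerated in C (flattened-index) order so argmax tie-breaks
    are deterministic.
    """
    try:
        mask = masks.structure_mask(structure)
    except KeyError:
        return None
    if not mask.any():
        return None
    idx = np.argwhere(mask)  # argwhere is C-ordered -> lowest flat index first
    return masks.world_from_voxel(idx)


def extreme_point(
    masks: LabelVolume,
    structure: str,
    axis: str,
    robust_fraction: float = DEFAULT_ROBUST_FRACTION,
) -> np.ndarray | None:
    """Centroid of the farthest ``robust_fraction`` slab along a signed axis.

    With ``robust_fraction == 0`` the single extreme voxel is returned
    (ties broken by lowest flattened index).  Returns None when the
    structure is absent.
    """
    coords = _structure_world_coords(masks, structure)
    if coords is None:
        return None
    ax, sign = _AXES[axis]
    proj = sign * coords[:, ax]
    if robust_fraction <= 0:
        return coords[int(np.argmax(proj))].copy()
    lo, hi = proj.min(), proj.max()
    cutoff = hi - robust_fraction * (hi - lo)
    slab = coords[proj >= cutoff]
    return slab.mean(axis=0)


def corner_point(
    masks: LabelVolume, structure: str, axis_a: str, axis_b: str
) -> np.ndarray | None:
    """Voxel maximising the sum of two bbox-normalised signed coordinates.

    Each axis is normalised by the mask's bounding-box extent along it so
    elongated structures do not bias the corner toward their long axis.
    Ties break by lowest flattened index; returns None when absent.
    """
    coords = _structure_world_coords(masks, structure)
    if coords is None:
        return None
    score = np.zeros(len(coords))
    for axis in (axis_a, axis_b):
        ax, sign = _AXES[axis]
        c = sign * coords[:, ax]
        extent = c.max() - c.min()
        score += (c - c.min()) / extent if extent > 0 else 0.0
    return coords[int(np.argmax(score))].copy()


def centroid_point(masks: LabelVolume, structure: str) -> np.ndarray | None:
    """Voxel centroid of a structure (world mm), or None when absent."""
    coords = _structure_world_coords(masks, structure)
    if coords is None:
        return None
    return coords.mean(axis=0)


def extract_auxiliary_landmarks(
    masks: LabelVolume,
    subject_id: str | None = None,
    heuristics: tuple[HeuristicSpec, ...] = DEFAULT_HEURISTICS,
) -> LandmarkSet:
    """Apply the heuristic table to organ masks; absent structures yield
    not-present landmarks."""
    coords = np.full((N_LANDMARKS, 3), np.nan)
    present = np.zeros(N_LANDMARKS, dtype=bool)
    for spec in heuristics:
        if spec.rule == "extreme_point":
            point = extreme_point(
                masks, spec.source_structure, spec.axes[0], spec.robust_fraction
            )
        elif spec.rule == "corner_point":
            point = corner_point(masks, spec.source_structure, *spec.axes)
        elif spec.rule == "centroid":
            point = centroid_point(masks, spec.source_structure)
        else:
            raise ValueError(f"unknown heuristic rule {spec.rule!r}")
        if point is None:
            continue
        i = landmark_index(spec.landmark)
        coords[i] = point
        present[i] = True
    if not present.any():
        logger.warning("no source structures found; zero auxiliary landmarks extracted")
    return LandmarkSet(subject_id or "aux", coords, present)
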