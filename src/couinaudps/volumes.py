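"""Label volumes and world/voxel coordinate conversion.

A :class:`LabelVolume` is a 3D integer array with a voxel-to-world affine
(mm) and an optional label-name map.  Voxel indices are 0-based and a
voxel's world coordinate is the coordinate of its centre.  Label 0 is
reserved for background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class LabelVolume:
    """3D integer label array with voxel-to-world affine (mm)."""

    labels: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if 0 in self.label_names:
            raise ValueError("label 0 is reserved for background")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_from_voxel(self, index) -> np.ndarray:
        """World coordinates (mm) of 0-based voxel indices (voxel centres).

        ``index`` may be one 3-vector or an (..., 3) integer array.
        """
        idx = np.asarray(index)
        scalar = idx.ndim == 1
        idx2 = np.atleast_2d(idx)
        if np.any(idx2 < 0) or np.any(idx2 >= np.array(self.labels.shape)):
            raise IndexError(f"voxel index out of bounds for shape {self.labels.shape}")
        world = idx2 @ self.affine[:3, :3].T + self.affine[:3, 3]
        return world[0] if scalar else world.reshape(idx.shape)

    def voxel_from_world(self, world) -> np.ndarray:
        """Nearest 0-based voxel index of world coordinates (mm)."""
        w = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        cont = np.atleast_2d(w) @ inv[:3, :3].T + inv[:3, 3]
        idx = np.rint(cont).astype(int)
        return idx[0] if w.ndim == 1 else idx.reshape(w.shape)

    def structure_mask(self, name_or_label: str | int) -> np.ndarray:
        """Boolean mask of one labelled structure."""
        if isinstance(name_or_label, str):
            matches = [k for k, v in self.label_names.items() if v == name_or_label]
            if not matches:
                raise KeyError(f"no structure named {name_or_label!r} in volume")
            label = matches[0]
        else:
            label = int(name_or_label)
        return self.labels == label

    def save_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.labels, dtype=np.int16), self.affine)
        nib.save(img, str(path))

    @classmethod
    def load_nifti(
        cls, path: str | Path, label_names: dict[int, str] | None = None
    ) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls(
            labels=np.rint(data).astype(np.int32),
            affine=np.asarray(img.affine, dtype=float),
            label_names=dict(label_names or {}),
        )


def save_density_nifti(log_density: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a float log-density map as NIfTI (heatmap export)."""
    img = nib.Nifti1Image(np.asarray(log_density, dtype=np.float32), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
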