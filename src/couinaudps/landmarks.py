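"""Canonical landmark registry and per-subject landmark sets.

The model works with 17 named anatomical landmarks: 8 "Couinaud" landmarks
that define the segment-dividing planes (points on the inferior vena cava,
gallbladder fossa, umbilical fissure, portal vein branches and hepatic
veins), and 9 "auxiliary" landmarks extracted from organ segmentations
(organ extreme points, corners and centroids) that constrain the spatial
model but never define a plane.

All coordinates are world-space millimetres.  The package fixes the world
axes to the RAS convention: +x patient Right, +y Anterior, +z Superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Couinaud-plane landmarks, fixed registry order (indices 0..7).
COUINAUD_LANDMARKS: tuple[str, ...] = (
    "IVCi",  # inferior vena cava, inferior point
    "IVCs",  # inferior vena cava, superior point
    "GBF",   # gallbladder fossa
    "UF",    # umbilical fissure
    "LPV",   # left portal vein branch point
    "RPV",   # right portal vein branch point
    "MHV",   # middle hepatic vein
    "RHV",   # right hepatic vein
)

#: Auxiliary landmarks extracted from organ masks (indices 8..16).
AUXILIARY_LANDMARKS: tuple[str, ...] = (
    "GB_TOP",        # top of gallbladder
    "HEART_BR",      # bottom-right corner of heart
    "LIVER_BR",      # liver bottom-right corner
    "LIVER_CENTER",  # liver centroid
    "LIVER_LC",      # liver left corner
    "PANC_TR",       # pancreas top-right corner
    "RKID_TOP",      # top of right kidney
    "PV_TOP",        # top of portal vein
    "LIVER_TR",      # liver top-right corner
)

#: Full canonical registry, fixed order; index into all model arrays.
ALL_LANDMARKS: tuple[str, ...] = COUINAUD_LANDMARKS + AUXILIARY_LANDMARKS

N_LANDMARKS: int = len(ALL_LANDMARKS)

LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_LANDMARKS)}


def landmark_index(name: str) -> int:
    """Registry index of a canonical landmark name.

    Raises
    ------
    KeyError
        If ``name`` is not one of the 17 canonical names.
    """
    try:
        return LANDMARK_INDEX[name]
    except KeyError:
        raise KeyError(
            f"unknown landmark name {name!r}; canonical names are "
            f"{', '.join(ALL_LANDMARKS)}"
        ) from None


@dataclass
class LandmarkSet:
    """One subject's named 3D landmark positions with presence flags.

    Parameters
    ----------
    subject_id : str
        Unique identifier of the subject.
    coords : (17, 3) ndarray
        World-space positions in mm, in registry order.  Rows whose
        presence flag is False carry no meaning (NaN by convention).
    present : (17,) ndarray of bool
        Presence flag per landmark.
    """

    subject_id: str
    coords: np.ndarray = field(
        default_factory=lambda: np.full((N_LANDMARKS, 3), np.nan)
    )
    present: np.ndarray = field(
        default_factory=lambda: np.zeros(N_LANDMARKS, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.coords.shape != (N_LANDMARKS, 3):
            raise ValueError(
                f"coords must have shape ({N_LANDMARKS}, 3), got {self.coords.shape}"
            )
        if self.present.shape != (N_LANDMARKS,):
            raise ValueError(
                f"present must have shape ({N_LANDMARKS},), got {self.present.shape}"
            )
        if not np.isfinite(self.coords[self.present]).all():
            raise ValueError(
                f"subject {self.subject_id!r}: present landmarks must have "
                "finite coordinates"
            )

    @classmethod
    def from_dict(
        cls, subject_id: str, positions: dict[str, object]
    ) -> "LandmarkSet":
        """Build from a ``{name: (x, y, z) mm}`` mapping; unnamed landmarks
        are marked not-present."""
        coords = np.full((N_LANDMARKS, 3), np.nan)
        present = np.zeros(N_LANDMARKS, dtype=bool)
        for name, pos in positions.items():
            i = landmark_index(name)
            coords[i] = np.asarray(pos, dtype=float)
            present[i] = True
        return cls(subject_id=subject_id, coords=coords, present=present)

    def __getitem__(self, name: str) -> np.ndarray:
        """Position of a present landmark (mm)."""
        i = landmark_index(name)
        if not self.present[i]:
            raise KeyError(f"landmark {name!r} is not present for subject "
                           f"{self.subject_id!r}")
        return self.coords[i].copy()

    def is_present(self, name: str) -> bool:
        return bool(self.present[landmark_index(name)])

    @property
    def present_names(self) -> list[str]:
        return [ALL_LANDMARKS[i] for i in np.flatnonzero(self.present)]

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def to_dict(self) -> dict[str, tuple[float, float, float]]:
        return {
            ALL_LANDMARKS[i]: tuple(self.coords[i])
            for i in np.flatnonzero(self.present)
        }

    def subset(self, names: list[str] | tuple[str, ...]) -> "LandmarkSet":
        """Copy with presence restricted to ``names`` (intersection)."""
        keep = np.zeros(N_LANDMARKS, dtype=bool)
        for name in names:
            keep[landmark_index(name)] = True
        return LandmarkSet(
            subject_id=self.subject_id,
            coords=self.coords.copy(),
            present=self.present & keep,
        )

    def translated(self, t) -> "LandmarkSet":
        """Copy with every present landmark shifted by ``t`` (mm)."""
        t = np.asarray(t, dtype=float)
        coords = self.coords.copy()
        coords[self.present] += t
        return LandmarkSet(self.subject_id, coords, self.present.copy())
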