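"""Plane-based Couinaud partition of a liver mask.

Five dividing planes are constructed from triples of the eight Couinaud
landmarks: the umbilical plane, the mid-hepatic plane, the right-hepatic
plane, and two transverse portal planes (one per portal branch, realised
as a plane through the branch point, the inferior vena cava point and an
axis-shifted copy of the branch point).  Each liver voxel is then assigned
to the unique segment whose plane-side conjunction it satisfies.

Segment 1 (caudate) is not defined by the landmarks and is deliberately
absent from the rule table; the reported volume percentages therefore
cover segments 2, 3, 4a, 4b, 5, 6, 7 and 8 and sum to 100% of the
labelled liver.

The default rule table is an explicit, overridable package choice (the
exact triples in surgical guides can be encoded via a custom table).  The
per-segment conjunctions are completed so they are mutually exclusive and
exhaustive by construction (a binary decision tree over the planes), which
guarantees the partition property for any non-degenerate landmark
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .landmarks import LandmarkSet, COUINAUD_LANDMARKS
from .volumes import LabelVolume

#: Segment label string -> integer code used in NIfTI output.
SEGMENT_CODES: dict[str, int] = {
    "2": 2, "3": 3, "4a": 41, "4b": 42, "5": 5, "6": 6, "7": 7, "8": 8,
}

#: Distance (mm) used to shift a portal branch landmark along the
#: inter-portal axis to define the transverse portal planes with only the
#: available landmarks.
PORTAL_SHIFT_MM = 50.0

#: Minimum triangle area (mm^2) below which a landmark triple is considered
#: collinear.
MIN_TRIANGLE_AREA = 1.0

#: Voxels within this absolute signed distance of a plane count as on-plane
#: and go to the positive side.
ON_PLANE_TOL = 1e-9


@dataclass
class Plane:
    """Oriented plane: point + unit normal, named."""

    point: np.ndarray
    normal: np.ndarray
    name: str

    def signed_distance(self, points) -> np.ndarray:
        """Signed distance (mm) of (..., 3) world points; positive on the
        normal side."""
        p = np.asarray(points, dtype=float)
        return (p - self.point) @ self.normal


def plane_from_triple(p1, p2, p3, orient_ref, name: str = "") -> Plane:
    """Plane through three points, oriented so ``orient_ref`` is positive.

    Raises when the triple is collinear (triangle area below 1 mm^2).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    cross = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(cross)
    if area <= MIN_TRIANGLE_AREA:
        raise ValueError(
            f"collinear landmark triple for plane {name or '<unnamed>'}: "
            f"triangle area {area:.3g} mm^2"
        )
    normal = cross / np.linalg.norm(cross)
    d = float((np.asarray(orient_ref, dtype=float) - p1) @ normal)
    if d == 0.0:
        raise ValueError(
            f"orientation reference lies on plane {name or '<unnamed>'}"
        )
    if d < 0:
        normal = -normal
    return Plane(point=p1.copy(), normal=normal, name=name)


@dataclass(frozen=True)
class PlaneSpec:
    """Recipe for one dividing plane from landmark names.

    A triple entry is one of
    - ``"NAME"`` — a landmark position;
    - ``("NAME", (dx, dy, dz))`` — a copy shifted by a fixed world vector
      (not rigid-equivariant; for custom tables only);
    - ``("NAME", "TOWARD", dist)`` — a copy shifted ``dist`` mm along the
      unit direction from NAME to TOWARD (landmark-derived, so the plane
      moves rigidly with the anatomy).
    """

    triple: tuple
    orient_ref: str


@dataclass
class SegmentRuleTable:
    """Plane recipes plus per-segment sign conjunctions.

    ``segments`` maps a segment label to a list of ``(plane_name, sign)``
    requirements; conjunctions are evaluated independently per voxel and
    must partition space (checked at assignment time).
    """

    planes: dict[str, PlaneSpec]
    segments: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    def build_planes(self, landmarks: LandmarkSet) -> dict[str, Plane]:
        built = {}
        for pname, spec in self.planes.items():
            pts = []
            for entry in spec.triple:
                if isinstance(entry, str):
                    pts.append(landmarks[entry])
                elif len(entry) == 3 and isinstance(entry[1], str):
                    base, toward, dist = entry
                    direction = landmarks[toward] - landmarks[base]
                    norm = np.linalg.norm(direction)
                    if norm < 1e-9:
                        raise ValueError(
                            f"degenerate shift direction {base}->{toward} "
                            f"for plane {pname}"
                        )
                    pts.append(landmarks[base] + float(dist) * direction / norm)
                else:
                    lname, shift = entry
                    pts.append(landmarks[lname] + np.asarray(shift, dtype=float))
            built[pname] = plane_from_triple(
                *pts, orient_ref=landmarks[spec.orient_ref], name=pname
            )
        return built

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "planes": {
                name: {
                    "triple": [
                        e
                        if isinstance(e, str)
                        else (
                            [e[0], e[1], float(e[2])]
                            if len(e) == 3 and isinstance(e[1], str)
                            else [e[0], list(e[1])]
                        )
                        for e in spec.triple
                    ],
                    "orient_ref": spec.orient_ref,
                }
                for name, spec in self.planes.items()
            },
            "segments": {
                seg: [[pname, int(sign)] for pname, sign in conj]
                for seg, conj in self.segments.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentRuleTable":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        planes = {}
        for name, spec in payload["planes"].items():
            triple = tuple(
                e
                if isinstance(e, str)
                else (
                    (e[0], e[1], float(e[2]))
                    if len(e) == 3 and isinstance(e[1], str)
                    else (e[0], tuple(float(c) for c in e[1]))
                )
                for e in spec["triple"]
            )
            planes[name] = PlaneSpec(triple=triple, orient_ref=spec["orient_ref"])
        segments = {
            str(seg): [(pname, int(sign)) for pname, sign in conj]
            for seg, conj in payload["segments"].items()
        }
        return cls(planes=planes, segments=segments)


def default_rule_table() -> SegmentRuleTable:
    """The package's default plane triples and segment conjunctions.

    Signs: +1 requires the voxel on the plane's positive (orient_ref)
    side, -1 the negative side.  The right-lobe conjunctions include the
    implied umbilical/mid-hepatic terms so the eight conjunctions are
    mutually exclusive and jointly exhaustive.
    """
    planes = {
        "UMBILICAL": PlaneSpec(("UF", "LPV", "IVCs"), "RPV"),
        "MIDHEPATIC": PlaneSpec(("GBF", "MHV", "IVCs"), "RHV"),
        "RIGHTHEPATIC": PlaneSpec(("RHV", "IVCi", "IVCs"), "GBF"),
        # transverse portal planes: portal branch point, IVCi, and a copy of
        # the branch point shifted along the inter-portal axis (a
        # landmark-derived direction, so the table is rigid-equivariant)
        "PORTAL_L": PlaneSpec(("LPV", "IVCi", ("LPV", "RPV", PORTAL_SHIFT_MM)), "IVCs"),
        "PORTAL_R": PlaneSpec(("RPV", "IVCi", ("RPV", "LPV", PORTAL_SHIFT_MM)), "IVCs"),
    }
    segments = {
        "2": [("UMBILICAL", -1), ("PORTAL_L", +1)],
        "3": [("UMBILICAL", -1), ("PORTAL_L", -1)],
        "4a": [("UMBILICAL", +1), ("MIDHEPATIC", -1), ("PORTAL_L", +1)],
        "4b": [("UMBILICAL", +1), ("MIDHEPATIC", -1), ("PORTAL_L", -1)],
        "5": [("UMBILICAL", +1), ("MIDHEPATIC", +1), ("RIGHTHEPATIC", -1),
              ("PORTAL_R", -1)],
        "8": [("UMBILICAL", +1), ("MIDHEPATIC", +1), ("RIGHTHEPATIC", -1),
              ("PORTAL_R", +1)],
        "6": [("UMBILICAL", +1), ("MIDHEPATIC", +1), ("RIGHTHEPATIC", +1),
              ("PORTAL_R", -1)],
        "7": [("UMBILICAL", +1), ("MIDHEPATIC", +1), ("RIGHTHEPATIC", +1),
              ("PORTAL_R", +1)],
    }
    return SegmentRuleTable(planes=planes, segments=segments)


@dataclass
class SegmentLabelMap:
    """Per-voxel Couinaud segment labels plus volume fractions."""

    labels: LabelVolume
    liver_voxel_count: int
    volumes_pct: dict[str, float]
    volumes_mm3: dict[str, float]
    voxel_counts: dict[str, int]

    def volume_table(self):
        """Volumes as a pandas DataFrame (segment, voxels, mm3, pct)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "segment": list(self.volumes_pct),
                "voxels": [self.voxel_counts[s] for s in self.volumes_pct],
                "volume_mm3": [self.volumes_mm3[s] for s in self.volumes_pct],
                "pct_of_liver": [self.volumes_pct[s] for s in self.volumes_pct],
            }
        )


def assign_segments(
    liver: LabelVolume,
    landmarks: LandmarkSet,
    rules: SegmentRuleTable | None = None,
    liver_label: int | str = 1,
) -> SegmentLabelMap:
    """Assign every liver voxel to a Couinaud segment.

    Each liver voxel centre (world mm) is tested against every segment's
    sign conjunction; on-plane voxels (|signed distance| < 1e-9 mm) count
    as positive.  Raises when the conjunctions overlap on more than 0.1%
    of liver voxels or leave any voxel unassigned.
    """
    rules = rules or default_rule_table()
    missing = [n for n in COUINAUD_LANDMARKS if not landmarks.is_present(n)]
    if missing:
        raise ValueError(f"Couinaud landmarks missing: {missing}")
    liver_mask = liver.structure_mask(liver_label)
    if not liver_mask.any():
        raise ValueError("liver mask is empty")

    planes = rules.build_planes(landmarks)
    idx = np.argwhere(liver_mask)
    world = liver.world_from_voxel(idx)

    # signed side per plane: True = positive side (incl. on-plane)
    side = {
        name: planes[name].signed_distance(world) >= -ON_PLANE_TOL
        for name in planes
    }

    n_liver = len(idx)
    match_count = np.zeros(n_liver, dtype=np.int8)
    assigned = np.zeros(n_liver, dtype=np.int16)
    counts: dict[str, int] = {}
    for seg, conj in rules.segments.items():
        sat = np.ones(n_liver, dtype=bool)
        for pname, sign in conj:
            sat &= side[pname] if sign > 0 else ~side[pname]
        match_count += sat
        newly = sat & (assigned == 0)
        assigned[newly] = SEGMENT_CODES[seg]
        counts[seg] = int(newly.sum())

    n_overlap = int((match_count > 1).sum())
    n_unassigned = int((assigned == 0).sum())
    if n_unassigned > 0 or n_overlap > 0.001 * n_liver:
        raise ValueError(
            "inconsistent rule table: "
            f"{n_unassigned} unassigned and {n_overlap} multiply-matched "
            f"of {n_liver} liver voxels"
        )

    out = np.zeros(liver.labels.shape, dtype=np.int16)
    out[tuple(idx.T)] = assigned
    voxvol = liver.voxel_volume_mm3
    volumes_mm3 = {s: counts[s] * voxvol for s in counts}
    volumes_pct = {s: 100.0 * counts[s] / n_liver for s in counts}
    label_names = {SEGMENT_CODES[s]: f"segment_{s}" for s in rules.segments}
    return SegmentLabelMap(
        labels=LabelVolume(out, liver.affine.copy(), label_names),
        liver_voxel_count=n_liver,
        volumes_pct=volumes_pct,
        volumes_mm3=volumes_mm3,
        voxel_counts=counts,
    )
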