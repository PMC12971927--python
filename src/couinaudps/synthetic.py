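"""Synthetic cohorts of 17-landmark anatomies and procedural organ masks.

No clinical data ship with the package, so every stage is exercised on a
generated population: a hand-crafted but anatomically plausible template
of the 17 landmarks (RAS world axes, mm; provenance: package constants,
not measured anatomy), perturbed per subject by subtype choice, Gaussian
landmark jitter, a global scale factor, a small rigid rotation and a
translation, with optional per-landmark missingness.

Procedural organ masks (liver, right kidney, pancreas, portal vein,
gallbladder, inferior vena cava, heart) are placed consistently with a
subject's landmarks so that the auxiliary-landmark heuristics recover the
generating positions to within about a voxel: ellipsoidal organs are
positioned such that the continuous argmax of each heuristic sits exactly
at the generating landmark, and the liver is a five-vertex convex
polytope whose corner vertices are the liver corner landmarks and whose
centroid is the LIVER_CENTER landmark.

Randomness uses per-subject substreams spawned from the master seed, so
subject ``i`` is identical regardless of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .landmarks import N_LANDMARKS, LandmarkSet
from .volumes import LabelVolume

#: Structure name -> integer label in generated mask volumes.
STRUCTURE_LABELS: dict[str, int] = {
    "liver": 1,
    "right kidney": 2,
    "pancreas": 3,
    "portal vein": 4,
    "gallbladder": 5,
    "inferior vena cava": 6,
    "heart": 7,
}

#: Template landmark geometry (mm, RAS: +x Right, +y Anterior, +z Superior).
#: Hand-crafted plausible adult-abdomen geometry; a package fixture, not
#: measured anatomy.
TEMPLATE_POSITIONS: dict[str, tuple[float, float, float]] = {
    "IVCi": (0.0, 0.0, -80.0),
    "IVCs": (0.0, 0.0, 75.0),
    "GBF": (35.0, 60.0, -45.0),
    "UF": (-30.0, 55.0, -25.0),
    "LPV": (-25.0, 25.0, -5.0),
    "RPV": (45.0, 15.0, -5.0),
    "MHV": (25.0, 35.0, 55.0),
    "RHV": (75.0, 25.0, 50.0),
    "GB_TOP": (38.0, 62.0, -55.0),
    "HEART_BR": (-20.0, 30.0, 80.0),
    "LIVER_BR": (-65.0, 40.0, -55.0),
    "LIVER_CENTER": (6.7, 30.0, -15.0),
    "LIVER_LC": (130.0, 20.0, -50.0),
    "PANC_TR": (-55.0, -45.0, -35.0),
    "RKID_TOP": (75.0, -35.0, -70.0),
    "PV_TOP": (10.0, 20.0, -8.0),
    "LIVER_TR": (-45.0, 30.0, 60.0),
}

#: Landmarks shifted in the second default subtype: the right-lobe vascular
#: landmarks plus the gallbladder and right-kidney points.  Models a
#: right-sided anatomical variant (portal/hepatic branching plus visceral
#: position) with a preserved liver envelope, so the variant is visible to
#: the auxiliary landmarks yet still biases a population-average model.
RIGHT_LOBE_LANDMARKS: tuple[str, ...] = (
    "GBF", "RPV", "RHV", "GB_TOP", "RKID_TOP",
)

#: Default lateral shift (mm) of the right-lobe landmarks in subtype 2.
SUBTYPE_SHIFT_MM = 15.0


def default_template(subject_id: str = "template") -> LandmarkSet:
    """The 17-landmark template anatomy, all landmarks present."""
    return LandmarkSet.from_dict(subject_id, TEMPLATE_POSITIONS)


def shifted_template(
    shift=(SUBTYPE_SHIFT_MM, 0.0, 0.0),
    names: tuple[str, ...] = RIGHT_LOBE_LANDMARKS,
    subject_id: str = "template_shifted",
) -> LandmarkSet:
    """Template variant with the named landmarks rigidly shifted (mm)."""
    positions = dict(TEMPLATE_POSITIONS)
    shift = np.asarray(shift, dtype=float)
    for name in names:
        positions[name] = tuple(np.asarray(positions[name]) + shift)
    return LandmarkSet.from_dict(subject_id, positions)


@dataclass
class CohortConfig:
    """Generator settings for a synthetic landmark cohort.

    Defaults model a two-subtype adult population: isotropic 5 mm
    per-landmark jitter, ~5% global size variation, small rigid pose
    changes, and a per-landmark missingness rate of 0.012 (the order of
    the missing-landmark rate in abdominal MRI cohorts where roughly one
    in five subjects lacks a single landmark).
    """

    n_subjects: int = 200
    templates: list[LandmarkSet] = field(
        default_factory=lambda: [default_template(), shifted_template()]
    )
    subtype_weights: tuple[float, ...] = (0.5, 0.5)
    jitter_sd: float = 5.0          # mm, isotropic per landmark
    global_scale_sd: float = 0.05   # lognormal sigma of the scale factor
    rotation_sd_deg: float = 2.0    # sd of each small rotation angle
    translation_sd_mm: float = 20.0
    missing_prob: float = 0.012     # per landmark
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_weights) - 1.0) > 1e-9:
            raise ValueError("subtype_weights must sum to 1")
        if len(self.subtype_weights) != len(self.templates):
            raise ValueError("one weight per template required")
        if self.jitter_sd < 0 or self.missing_prob < 0 or self.missing_prob > 1:
            raise ValueError("invalid jitter_sd or missing_prob")


def two_subtype_benchmark_config(
    n_subjects: int = 200, jitter_sd: float = 5.0, seed: int = 0
) -> CohortConfig:
    """The two-subtype evaluation world: 15 mm subtype separation of the
    right-lobe landmarks, isotropic jitter, translation-only pose, no
    missingness.  Used to demonstrate the personalization benefit."""
    return CohortConfig(
        n_subjects=n_subjects,
        jitter_sd=jitter_sd,
        global_scale_sd=0.0,
        rotation_sd_deg=0.0,
        translation_sd_mm=20.0,
        missing_prob=0.0,
        seed=seed,
    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))
    )


def generate_cohort(config: CohortConfig) -> list[LandmarkSet]:
    """Draw a cohort of landmark sets from the configured population.

    Subject i is ``scale * R @ (template_z + jitter) + translation`` with
    the subtype z, jitter, pose and missingness all drawn from subject i's
    own substream of the master seed.
    """
    if config.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    weights = np.asarray(config.subtype_weights, dtype=float)
    subjects = []
    for i in range(config.n_subjects):
        rng = _subject_rng(config.seed, i)
        z = int(rng.choice(len(weights), p=weights))
        template = config.templates[z]
        coords = template.coords.copy()
        coords += rng.normal(scale=config.jitter_sd, size=coords.shape)
        scale = float(np.exp(rng.normal(scale=config.global_scale_sd)))
        rotvec = np.deg2rad(rng.normal(scale=config.rotation_sd_deg, size=3))
        R = Rotation.from_rotvec(rotvec).as_matrix()
        coords = scale * coords @ R.T
        coords += rng.normal(scale=config.translation_sd_mm, size=3)
        present = template.present & (rng.random(N_LANDMARKS) >= config.missing_prob)
        coords[~present] = np.nan
        subjects.append(LandmarkSet(f"synth_{i:04d}", coords, present))
    return subjects


def subject_subtypes(config: CohortConfig) -> np.ndarray:
    """Subtype index drawn for each subject (replays the per-subject RNG)."""
    weights = np.asarray(config.subtype_weights, dtype=float)
    return np.array(
        [
            int(_subject_rng(config.seed, i).choice(len(weights), p=weights))
            for i in range(config.n_subjects)
        ]
    )


# ---------------------------------------------------------------------------
# procedural organ masks


def _ellipsoid_mask(world: np.ndarray, center, semiaxes) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    s = np.asarray(semiaxes, dtype=float)
    return (((world - c) / s) ** 2).sum(axis=-1) <= 1.0


def _vertex_blob_mask(world: np.ndarray, vertex, e1, e2, half_thickness: float) -> np.ndarray:
    """Convex five-vertex polytope with a true 3D vertex at ``vertex``.

    Two tetrahedra over the triangle (vertex, vertex+e1, vertex+e2) with
    apexes offset from the triangle centroid along +-y.  Used for organs
    whose landmark is a corner point: a polytope vertex pins all three
    coordinates of the heuristic argmax (smooth or box-like surfaces leave
    the off-axis coordinate underdetermined on the voxel grid).
    """
    v = np.asarray(vertex, dtype=float)
    p1 = v + np.asarray(e1, dtype=float)
    p2 = v + np.asarray(e2, dtype=float)
    centroid = (v + p1 + p2) / 3.0
    a1 = centroid + np.array([0.0, half_thickness, 0.0])
    a2 = centroid - np.array([0.0, half_thickness, 0.0])
    return _tetra_mask(world, v, p1, p2, a1) | _tetra_mask(world, v, p1, p2, a2)


def _tetra_mask(world: np.ndarray, v0, v1, v2, v3) -> np.ndarray:
    """Points inside the tetrahedron (barycentric test)."""
    mat = np.column_stack([v1 - v0, v2 - v0, v3 - v0])
    bary = np.linalg.solve(mat, (world - v0).T).T
    inside = (bary >= 0.0).all(axis=-1) & (bary.sum(axis=-1) <= 1.0)
    return inside


def _liver_polytope_masks(world, landmarks: LandmarkSet, half_thickness: float = 60.0):
    """Liver body: two tetrahedra over the corner-landmark triangle.

    The three corner landmarks are polytope vertices (so the corner
    heuristics recover them to within about a voxel); the two apexes sit
    symmetrically on the triangle normal through the corner mean, which
    keeps the vertex cones wide and stable under landmark jitter.  The
    body's centroid is the corner mean; the LIVER_CENTER constraint is
    met separately by a pad (see ``generate_subject_masks``).
    """
    br = landmarks["LIVER_BR"]
    lc = landmarks["LIVER_LC"]
    tr = landmarks["LIVER_TR"]
    t = (br + lc + tr) / 3.0
    n = np.cross(lc - br, tr - br)
    n = n / np.linalg.norm(n)
    a1 = t + half_thickness * n
    a2 = t - half_thickness * n
    return _tetra_mask(world, br, lc, tr, a1) | _tetra_mask(world, br, lc, tr, a2)


def _solve_centroid(
    world: np.ndarray,
    body: np.ndarray,
    free: np.ndarray,
    target: np.ndarray,
    corner_points: list[np.ndarray],
    grid_shape: tuple[int, ...],
    max_iter: int = 40,
    tol_mm: float = 0.5,
) -> np.ndarray:
    """Adjust a mask so its voxel centroid lands on ``target``.

    The polytope body's centroid sits at the corner-landmark mean and is
    further biased by vessel holes and corner caps, while per-landmark
    jitter moves LIVER_CENTER independently; the gap is closed by
    transferring voxels between the mask and an adjustable pool: a
    dilated shell around the body (voxels that may be added) plus the
    body interior (voxels that may be removed).  Each iteration flips
    the pool voxels with the largest lever along the current residual,
    covering half the residual at a time; flips are reversible, so the
    damped iteration converges without exhausting the pool.  The pool
    is confined to the middle of the body's x/z bounding box (the
    corner heuristics use x and z only, so the adjustment can never
    become a corner extreme) and keeps clear of the corner vertices and
    of the target voxel itself.
    """
    from scipy import ndimage

    body_w = world[body]
    lo = body_w.min(axis=0)
    hi = body_w.max(axis=0)
    inset = 0.15 * (hi - lo)
    allowed = (
        (world[:, 0] > lo[0] + inset[0]) & (world[:, 0] < hi[0] - inset[0])
        & (world[:, 2] > lo[2] + inset[2]) & (world[:, 2] < hi[2] - inset[2])
    )
    protect = np.linalg.norm(world - target, axis=-1) < 12.0
    for cp in corner_points:
        protect |= np.linalg.norm(world - cp, axis=-1) < 30.0

    shell = ndimage.binary_dilation(
        body.reshape(grid_shape), iterations=12
    ).reshape(-1)
    pool = np.flatnonzero(
        ((shell & ~body & free) | body) & allowed & ~protect
    )
    pool_world = world[pool]

    current = body.copy()
    for _ in range(max_iter):
        c = world[current].mean(axis=0)
        r = target - c
        norm_r = float(np.linalg.norm(r))
        if norm_r < tol_mm:
            break
        r_hat = r / norm_r
        need = 0.5 * current.sum() * norm_r
        on = current[pool]
        # flipping a voxel on adds (v - target) to the lever sum; off negates
        gain = np.where(on, -1.0, 1.0) * ((pool_world - target) @ r_hat)
        order = np.argsort(gain)[::-1]
        gains = gain[order]
        positive = gains > 0
        cum = np.cumsum(np.where(positive, gains, 0.0))
        if cum[-1] <= 0:
            break
        k = min(int(np.searchsorted(cum, need)) + 1, len(order))
        chosen = pool[order[:k][positive[:k]]]
        current[chosen] = ~current[chosen]
    return current


#: Corner-cap cone: length (mm) and half-angle (deg) of the blunting cone
#: added at every corner-landmark vertex.
_CAP_LENGTH = 32.0
_CAP_HALF_ANGLE = 40.0


def _cap_mask(world: np.ndarray, vertex, axis_dir) -> np.ndarray:
    """Corner-blunting cap: a cone plus a thin axial spike.

    The cone gives the vertex a wide solid angle; the spike (radius just
    over a voxel diagonal) guarantees that some mask voxel lies within
    about one voxel of the vertex for every grid phase, which bounds the
    corner-heuristic recovery error.
    """
    apex = np.asarray(vertex, dtype=float)
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    rel = world - apex
    s = rel @ d
    radial = np.linalg.norm(rel - s[:, None] * d, axis=-1)
    cone = (s >= 0.0) & (s <= _CAP_LENGTH) & (
        radial <= s * np.tan(np.deg2rad(_CAP_HALF_ANGLE))
    )
    spike = (s >= 0.0) & (s <= _CAP_LENGTH) & (radial <= 3.6)
    return cone | spike


def _corner_cap_axis(signs: tuple[float, float], extents: tuple[float, float]) -> np.ndarray:
    """Axis for a corner-blunting cone: the negated gradient of the corner
    objective in world units.

    The corner heuristic maximises ``sign_x * x / ext_x + sign_z * z /
    ext_z``; a cone whose axis points down that gradient keeps every cap
    voxel strictly below the vertex's score (radial offsets are
    score-neutral to first order), so the cap can never steal the argmax
    while still blunting the vertex for the voxel grid.
    """
    gx = signs[0] / max(extents[0], 1e-6)
    gz = signs[1] / max(extents[1], 1e-6)
    return np.array([-gx, 0.0, -gz])

#: Ellipsoid semiaxes (mm) for organs whose landmark is a top point.
ORGAN_SEMIAXES: dict[str, tuple[float, float, float | None]] = {
    "gallbladder": (16.0, 16.0, 28.0),
    "right kidney": (24.0, 24.0, 42.0),
    "portal vein": (8.0, 8.0, 24.0),
    "inferior vena cava": (11.0, 11.0, None),  # z semiaxis from IVCi..IVCs
}

#: Vertex-blob edges (mm) for organs whose landmark is a corner point:
#: (edge1, edge2, half_thickness); both edges point away from the corner.
ORGAN_BLOBS: dict[str, tuple[tuple[float, float, float], tuple[float, float, float], float]] = {
    "heart": ((70.0, 0.0, 30.0), (25.0, 0.0, 75.0), 38.0),
    "pancreas": ((90.0, 0.0, -15.0), (35.0, 0.0, -40.0), 20.0),
}


def generate_subject_masks(
    landmarks: LandmarkSet,
    grid_shape: tuple[int, int, int] | None = None,
    spacing: float = 4.0,
    origin=None,
) -> LabelVolume:
    """Procedural organ label volume consistent with a subject's landmarks.

    Organs are painted in a fixed order with earlier structures excluded
    from later ones, so masks are pairwise disjoint by construction (the
    liver is painted last and acquires holes where the portal vein and
    vena cava run through it).  Structures whose defining landmarks are
    missing are omitted.
    """
    pts = landmarks.coords[landmarks.present]
    if len(pts) == 0:
        raise ValueError("cannot build masks for a subject with no landmarks")
    margin = 140.0
    if origin is None or grid_shape is None:
        lo = pts.min(axis=0) - margin
        hi = pts.max(axis=0) + margin
        origin = lo
        grid_shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    origin = np.asarray(origin, dtype=float)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = origin

    hi_world = origin + (np.asarray(grid_shape) - 1) * spacing
    if np.any(pts < origin) or np.any(pts > hi_world):
        raise ValueError("grid too small to contain the subject's organs")

    shape = tuple(int(s) for s in grid_shape)
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    world = (
        np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * spacing + origin
    )

    labels = np.zeros(world.shape[0], dtype=np.int16)

    def paint(structure: str, mask: np.ndarray) -> None:
        free = mask & (labels == 0)
        labels[free] = STRUCTURE_LABELS[structure]

    def have(*names: str) -> bool:
        return all(landmarks.is_present(n) for n in names)

    # vessels first so the liver is painted around them
    if have("IVCi", "IVCs"):
        ivci, ivcs = landmarks["IVCi"], landmarks["IVCs"]
        center = (ivci + ivcs) / 2.0
        a, b, _ = ORGAN_SEMIAXES["inferior vena cava"]
        cz = abs(ivcs[2] - ivci[2]) / 2.0 + 10.0
        paint("inferior vena cava", _ellipsoid_mask(world, center, (a, b, cz)))
    if have("PV_TOP"):
        a, b, c = ORGAN_SEMIAXES["portal vein"]
        center = landmarks["PV_TOP"] - np.array([0.0, 0.0, c])
        paint("portal vein", _ellipsoid_mask(world, center, (a, b, c)))
    if have("GB_TOP"):
        a, b, c = ORGAN_SEMIAXES["gallbladder"]
        center = landmarks["GB_TOP"] - np.array([0.0, 0.0, c])
        paint("gallbladder", _ellipsoid_mask(world, center, (a, b, c)))
    if have("HEART_BR"):
        e1, e2, half = ORGAN_BLOBS["heart"]
        v = landmarks["HEART_BR"]
        blob = _vertex_blob_mask(world, v, e1, e2, half)
        ext = (max(abs(e1[0]), abs(e2[0])), max(abs(e1[2]), abs(e2[2])))
        axis = _corner_cap_axis((-1.0, -1.0), ext)  # HEART_BR is a (-x,-z) corner
        blob |= _cap_mask(world, v, axis)
        paint("heart", blob)
    if have("RKID_TOP"):
        a, b, c = ORGAN_SEMIAXES["right kidney"]
        center = landmarks["RKID_TOP"] - np.array([0.0, 0.0, c])
        paint("right kidney", _ellipsoid_mask(world, center, (a, b, c)))
    if have("PANC_TR"):
        e1, e2, half = ORGAN_BLOBS["pancreas"]
        v = landmarks["PANC_TR"]
        blob = _vertex_blob_mask(world, v, e1, e2, half)
        ext = (max(abs(e1[0]), abs(e2[0])), max(abs(e1[2]), abs(e2[2])))
        axis = _corner_cap_axis((-1.0, 1.0), ext)  # PANC_TR is a (-x,+z) corner
        blob |= _cap_mask(world, v, axis)
        paint("pancreas", blob)
    if have("LIVER_BR", "LIVER_LC", "LIVER_TR"):
        corner_signs = {"LIVER_BR": (-1.0, -1.0), "LIVER_LC": (1.0, -1.0),
                        "LIVER_TR": (-1.0, 1.0)}
        corners = [landmarks[n] for n in corner_signs]
        cs = np.asarray(corners)
        ext = (cs[:, 0].max() - cs[:, 0].min(), cs[:, 2].max() - cs[:, 2].min())
        body = _liver_polytope_masks(world, landmarks)
        # blunt each corner vertex with a wide cone so the voxel grid
        # always samples close to it
        for name, signs in corner_signs.items():
            body |= _cap_mask(world, landmarks[name], _corner_cap_axis(signs, ext))
        body &= labels == 0
        if have("LIVER_CENTER"):
            body = _solve_centroid(
                world, body, labels == 0, landmarks["LIVER_CENTER"], corners, shape
            )
        labels[body] = STRUCTURE_LABELS["liver"]

    names = {v: k for k, v in STRUCTURE_LABELS.items()}
    return LabelVolume(
        labels=labels.reshape(shape), affine=affine, label_names=names
    )
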