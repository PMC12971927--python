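"""Product-of-Gaussians landmark inference.

Each known landmark ``k`` votes for the unknown landmark ``u`` with a
trivariate Gaussian conditional density centred at ``l_k + mu[u, k]`` with
covariance ``sigma[u, k]``.  The spatial probability map of ``u`` is the
product of the votes over all known landmarks, and the predicted position
is its mode.  Because a product of Gaussians is (up to normalisation) a
Gaussian, the mode has a closed form:

    precision = sum_k sigma_{u,k}^{-1}
    mean      = precision^{-1} sum_k sigma_{u,k}^{-1} (l_k + mu_{u,k})

All densities are handled in the log domain; the voxel-grid heatmap path
exists for export and as an independent check of the closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .cohort import DisplacementModel
from .landmarks import LandmarkSet, landmark_index
from .volumes import LabelVolume

logger = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Trivariate normal log-density via Cholesky; ``x`` is (..., 3)."""
    chol = linalg.cholesky(cov, lower=True)
    dev = np.asarray(x, dtype=float) - mean
    sol = linalg.solve_triangular(chol, dev.reshape(-1, 3).T, lower=True)
    maha = np.sum(sol**2, axis=0).reshape(dev.shape[:-1])
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (3.0 * _LOG_2PI + logdet + maha)


def conditional_log_density(
    u: str,
    k: str,
    l_k,
    model: DisplacementModel,
    v,
) -> np.ndarray:
    """Log conditional density of landmark ``u`` at ``v`` given ``k`` at ``l_k``.

    The density is a 3D Gaussian with mean ``l_k + mu[u, k]`` and
    covariance ``sigma[u, k]``.  ``v`` may be a single 3-vector or an
    (..., 3) array of evaluation points.
    """
    mu, sigma = model.pair(u, k)
    mean = np.asarray(l_k, dtype=float) + mu
    out = _mvn_logpdf(np.asarray(v, dtype=float), mean, sigma)
    return out if out.ndim else float(out)


@dataclass
class FusedGaussian:
    """Closed form of the product of contributor Gaussians."""

    precision: np.ndarray  # (3, 3), mm^-2
    mean: np.ndarray       # (3,), mm
    contributors: list[str]

    @property
    def covariance(self) -> np.ndarray:
        return linalg.inv(self.precision)


def usable_contributors(
    u: str, known: LandmarkSet, model: DisplacementModel
) -> list[str]:
    """Known landmarks with a usable displacement model toward ``u``."""
    iu = landmark_index(u)
    return [
        k
        for k in known.present_names
        if k != u and model.usable[iu, landmark_index(k)]
    ]


def fuse(u: str, known: LandmarkSet, model: DisplacementModel) -> FusedGaussian:
    """Fuse the conditional Gaussians of all usable contributors for ``u``.

    The fused mean is the mode of the product density over continuous
    space (precision-weighted average of the contributors' predicted
    positions).
    """
    contributors = usable_contributors(u, known, model)
    if not contributors:
        raise ValueError(
            f"landmark {u!r} unpredictable: no usable contributor among "
            f"known landmarks {known.present_names}"
        )
    iu = landmark_index(u)
    precision = np.zeros((3, 3))
    weighted = np.zeros(3)
    for k in contributors:
        ik = landmark_index(k)
        pred = known[k] + model.mu[iu, ik]
        lam = linalg.inv(model.sigma[iu, ik])
        precision += lam
        weighted += lam @ pred
    mean = linalg.solve(precision, weighted, assume_a="pos")
    return FusedGaussian(precision=precision, mean=mean, contributors=contributors)


@dataclass
class ProbabilityMap:
    """Per-voxel log-probability map of one landmark on a voxel grid."""

    log_density: np.ndarray
    affine: np.ndarray
    landmark: str
    contributor: str | None = None  # None for the combined map

    def argmax_world(self) -> np.ndarray:
        """World position (mm) of the map's maximum voxel.

        Ties are broken by lowest flattened index (np.argmax convention).
        """
        idx = np.unravel_index(int(np.argmax(self.log_density)), self.log_density.shape)
        hom = np.array([idx[0], idx[1], idx[2], 1.0])
        return (self.affine @ hom)[:3]


def _default_grid(known: LandmarkSet, spacing: float = 2.0, margin: float = 100.0) -> LabelVolume:
    """A spacing-mm grid spanning all known landmarks plus a margin."""
    pts = known.coords[known.present]
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = lo
    return LabelVolume(labels=np.zeros(shape, dtype=np.int16), affine=affine)


def heatmap(
    u: str,
    known: LandmarkSet,
    model: DisplacementModel,
    grid: LabelVolume | None = None,
) -> tuple[ProbabilityMap, list[ProbabilityMap]]:
    """Combined and per-contributor log-probability maps on a voxel grid.

    The combined map is the voxelwise sum of the per-contributor log maps
    (i.e. the log of the product density); its argmax agrees with the
    closed-form :func:`fuse` mean to within one voxel when the grid covers
    the fused mode.
    """
    fused = fuse(u, known, model)
    if grid is None:
        grid = _default_grid(known)

    shape = grid.labels.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    world = grid.world_from_voxel(idx).reshape(shape + (3,))

    # warn when the grid cannot contain the fused mode +- 3 sigma
    sd = np.sqrt(np.diag(fused.covariance))
    lo, hi = world.reshape(-1, 3).min(axis=0), world.reshape(-1, 3).max(axis=0)
    if np.any(fused.mean - 3 * sd < lo) or np.any(fused.mean + 3 * sd > hi):
        logger.warning(
            "heatmap grid for %s does not cover the fused mean +- 3 sigma", u
        )

    iu = landmark_index(u)
    per_contributor = []
    combined = np.zeros(shape)
    for k in fused.contributors:
        ik = landmark_index(k)
        mean = known[k] + model.mu[iu, ik]
        logp = _mvn_logpdf(world, mean, model.sigma[iu, ik])
        per_contributor.append(
            ProbabilityMap(log_density=logp, affine=grid.affine.copy(),
                           landmark=u, contributor=k)
        )
        combined = combined + logp
    combined_map = ProbabilityMap(
        log_density=combined, affine=grid.affine.copy(), landmark=u, contributor=None
    )
    return combined_map, per_contributor


def predict_missing(
    partial: LandmarkSet,
    model: DisplacementModel,
    targets: list[str] | tuple[str, ...],
) -> tuple[LandmarkSet, dict[str, str]]:
    """Predict each target landmark independently from the present ones.

    Contributors are only the landmarks present in ``partial``; predicted
    landmarks are never chained back in as contributors.  Returns the
    completed landmark set and a provenance map
    ``{name: "observed" | "predicted" | "unpredictable"}``.
    """
    for t in targets:
        if partial.is_present(t):
            raise ValueError(f"target {t!r} is already present in the input set")
    coords = partial.coords.copy()
    present = partial.present.copy()
    provenance = {name: "observed" for name in partial.present_names}
    for t in targets:
        try:
            fused = fuse(t, partial, model)
        except ValueError as exc:
            logger.warning("cannot predict %s: %s", t, exc)
            provenance[t] = "unpredictable"
            continue
        it = landmark_index(t)
        coords[it] = fused.mean
        present[it] = True
        provenance[t] = "predicted"
    return LandmarkSet(partial.subject_id, coords, present), provenance
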