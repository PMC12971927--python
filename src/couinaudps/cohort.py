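"""Cohort displacement matrix and the fitted Gaussian displacement model.

The spatial model is built from pairwise landmark displacements, not
absolute positions: the information lives in the geometric relations
between landmarks, which makes the model invariant to patient position on
the scanner table and independent of imaging modality.

For a cohort of P subjects and N = 17 landmarks, the data matrix holds the
3D displacement from landmark ``u`` to landmark ``k`` for every subject, a
P x N x N x 3 array with a validity mask.  Fitting reduces each ordered
pair (u, k) to a trivariate Gaussian with mean displacement ``mu[u, k]``
and covariance ``sigma[u, k]`` over the subjects where both landmarks are
present; missing landmarks are simply excluded from the per-pair sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landmarks import ALL_LANDMARKS, N_LANDMARKS, LandmarkSet, landmark_index

#: Default Tikhonov regularisation added to every fitted covariance (mm^2).
DEFAULT_LAMBDA = 1.0

#: Minimum valid samples for a pair's covariance to be considered usable.
#: A 3D covariance needs at least 4 points to be generically full rank.
MIN_SAMPLES = 4

ARCHIVE_FORMAT_VERSION = "couinaudps-model-1"


@dataclass
class CohortMatrix:
    """Pairwise displacement data matrix for a cohort.

    Attributes
    ----------
    displacements : (P, N, N, 3) ndarray
        ``displacements[p, u, k]`` is ``position_k - position_u`` (mm) for
        subject ``p``; NaN where invalid.
    valid : (P, N, N) ndarray of bool
        True iff both landmarks of the pair are present for the subject.
    subject_ids : list of str
    """

    displacements: np.ndarray
    valid: np.ndarray
    subject_ids: list[str]

    @property
    def n_subjects(self) -> int:
        return self.displacements.shape[0]

    def without_subject(self, subject_id: str) -> "CohortMatrix":
        """Leave-one-out submatrix removal: drop one subject's slice."""
        if subject_id not in self.subject_ids:
            raise KeyError(f"subject {subject_id!r} not in cohort")
        keep = [i for i, s in enumerate(self.subject_ids) if s != subject_id]
        return CohortMatrix(
            displacements=self.displacements[keep],
            valid=self.valid[keep],
            subject_ids=[self.subject_ids[i] for i in keep],
        )

    def select_subjects(self, subject_ids: list[str]) -> "CohortMatrix":
        """Submatrix restricted to the given subjects, in the given order."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in subject_ids]
        return CohortMatrix(
            displacements=self.displacements[rows],
            valid=self.valid[rows],
            subject_ids=list(subject_ids),
        )


def build_cohort_matrix(subjects: list[LandmarkSet]) -> CohortMatrix:
    """Assemble the P x N x N x 3 displacement matrix from landmark sets.

    ``displacements[p, u, k] = l_k - l_u`` wherever both landmarks are
    present; ``valid[p, u, k]`` records availability.  Self-displacements
    are stored as zeros (and are never used in inference).
    """
    if len(subjects) == 0:
        raise ValueError("cannot build a cohort matrix from zero subjects")
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")

    P = len(subjects)
    disp = np.full((P, N_LANDMARKS, N_LANDMARKS, 3), np.nan)
    valid = np.zeros((P, N_LANDMARKS, N_LANDMARKS), dtype=bool)
    for p, subj in enumerate(subjects):
        pres = subj.present
        coords = np.where(pres[:, None], subj.coords, 0.0)
        pair_ok = pres[:, None] & pres[None, :]
        d = coords[None, :, :] - coords[:, None, :]  # [u, k] = l_k - l_u
        disp[p][pair_ok] = d[pair_ok]
        valid[p] = pair_ok
    return CohortMatrix(displacements=disp, valid=valid, subject_ids=ids)


@dataclass
class DisplacementModel:
    """Fitted pairwise Gaussian displacement model.

    Attributes
    ----------
    mu : (N, N, 3) ndarray
        ``mu[u, k]`` is the mean position of landmark u relative to
        landmark k (mm), i.e. ``E[l_u - l_k]``, so the conditional mean
        of u given k at ``l_k`` is ``l_k + mu[u, k]``.  NaN for pairs
        with no samples.
    sigma : (N, N, 3, 3) ndarray
        Regularised sample covariance per ordered pair (mm^2); NaN where
        fewer than 2 samples.
    n_samples : (N, N) ndarray of int
        Valid sample count per pair.
    usable : (N, N) ndarray of bool
        True where ``n_samples >= min_samples`` and u != k; only usable
        pairs participate in inference.
    regularization : float
        The lambda (mm^2) added to the covariance diagonal.
    """

    mu: np.ndarray
    sigma: np.ndarray
    n_samples: np.ndarray
    usable: np.ndarray
    regularization: float
    min_samples: int = MIN_SAMPLES

    def pair(self, u: str, k: str) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) for an ordered usable pair of landmark names."""
        iu, ik = landmark_index(u), landmark_index(k)
        if not self.usable[iu, ik]:
            raise ValueError(
                f"pair ({u}, {k}) is unusable: "
                f"{int(self.n_samples[iu, ik])} valid samples "
                f"(minimum {self.min_samples})"
            )
        return self.mu[iu, ik].copy(), self.sigma[iu, ik].copy()

    def save(self, path: str | Path) -> None:
        """Write the model archive (NumPy .npz; arrays round-trip bit-exact)."""
        np.savez(
            path,
            mu=self.mu,
            sigma=self.sigma,
            n_samples=self.n_samples,
            usable=self.usable,
            regularization=np.float64(self.regularization),
            min_samples=np.int64(self.min_samples),
            landmark_names=np.array(ALL_LANDMARKS),
            format_version=np.array(ARCHIVE_FORMAT_VERSION),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DisplacementModel":
        with np.load(path, allow_pickle=False) as z:
            version = str(z["format_version"])
            if version != ARCHIVE_FORMAT_VERSION:
                raise ValueError(f"unsupported model archive version {version!r}")
            names = [str(n) for n in z["landmark_names"]]
            if tuple(names) != ALL_LANDMARKS:
                raise ValueError("model archive landmark registry mismatch")
            return cls(
                mu=z["mu"],
                sigma=z["sigma"],
                n_samples=z["n_samples"],
                usable=z["usable"],
                regularization=float(z["regularization"]),
                min_samples=int(z["min_samples"]),
            )


def fit_displacement_model(
    matrix: CohortMatrix,
    lambda_reg: float = DEFAULT_LAMBDA,
    min_samples: int = MIN_SAMPLES,
) -> DisplacementModel:
    """Fit per-pair Gaussians to a cohort displacement matrix.

    For each ordered pair (u, k): ``mu`` is the sample mean over subjects
    with the pair valid, ``sigma`` the sample covariance (n-1 denominator)
    plus ``lambda_reg * I``.  Pairs with fewer than ``min_samples`` valid
    samples are flagged unusable and excluded from inference; pairs with
    zero samples carry NaN statistics, never silent zeros.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be non-negative")
    # matrix stores d[p, u, k] = l_k - l_u; the model wants mu[u, k] =
    # E[l_u - l_k] (position of u relative to k), i.e. the [k, u] slice
    d = matrix.displacements.transpose(0, 2, 1, 3)
    v = matrix.valid.transpose(0, 2, 1)
    n = v.sum(axis=0)  # (N, N)

    d0 = np.where(v[..., None], d, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = d0.sum(axis=0) / n[..., None]
    mu[n == 0] = np.nan

    centered = np.where(v[..., None], d0 - mu[None], 0.0)
    # sigma[u,k] = sum_p c c^T / (n-1) + lambda I
    outer = np.einsum("puki,pukj->ukij", centered, centered)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = outer / np.maximum(n - 1, 1)[..., None, None]
    sigma = sigma + lambda_reg * np.eye(3)
    sigma[n < 2] = np.nan

    usable = n >= min_samples
    np.fill_diagonal(usable, False)
    return DisplacementModel(
        mu=mu,
        sigma=sigma,
        n_samples=n.astype(int),
        usable=usable,
        regularization=float(lambda_reg),
        min_samples=int(min_samples),
    )
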