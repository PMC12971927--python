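"""Model/Results front end for the pictorial-structures landmark model.

:class:`PictorialStructuresModel` holds a cohort of landmark sets (the
training data); :meth:`~PictorialStructuresModel.fit` estimates the
pairwise Gaussian displacement parameters and returns a
:class:`PictorialStructuresResults` carrying the estimates, per-pair
sample counts, and prediction / heatmap / summary methods.

    >>> cohort = generate_cohort(CohortConfig(n_subjects=50, seed=1))
    >>> model = PictorialStructuresModel(cohort)
    >>> res = model.fit()
    >>> completed, provenance = res.predict(aux_only_case)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_LAMBDA,
    MIN_SAMPLES,
    CohortMatrix,
    DisplacementModel,
    build_cohort_matrix,
    fit_displacement_model,
)
from .inference import FusedGaussian, ProbabilityMap, fuse, heatmap, predict_missing
from .landmarks import ALL_LANDMARKS, COUINAUD_LANDMARKS, LandmarkSet
from .personalize import DEFAULT_SUBSET_SIZE, select_similar


class PictorialStructuresModel:
    """Pictorial-structures displacement model over a landmark cohort.

    Parameters
    ----------
    subjects : list of LandmarkSet
        Training cohort; missing landmarks are handled per pair.
    lambda_reg : float
        Covariance regularisation added to every pair (mm^2).
    min_samples : int
        Minimum valid samples for a pair to be usable in inference.
    """

    def __init__(
        self,
        subjects: list[LandmarkSet],
        lambda_reg: float = DEFAULT_LAMBDA,
        min_samples: int = MIN_SAMPLES,
    ) -> None:
        self.subjects = list(subjects)
        self.lambda_reg = float(lambda_reg)
        self.min_samples = int(min_samples)
        self.matrix: CohortMatrix = build_cohort_matrix(self.subjects)

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "PictorialStructuresModel":
        """Build from a directory of landmark CSV/JSON files."""
        from .io import read_cohort_dir

        return cls(read_cohort_dir(directory), **kwargs)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def fit(self) -> "PictorialStructuresResults":
        """Fit the per-pair Gaussian displacement parameters."""
        params = fit_displacement_model(
            self.matrix, lambda_reg=self.lambda_reg, min_samples=self.min_samples
        )
        return PictorialStructuresResults(self, params)

    def fit_personalized(
        self, query: LandmarkSet, n: int = DEFAULT_SUBSET_SIZE
    ) -> "PictorialStructuresResults":
        """Fit on the ``n`` training cases most similar to ``query``.

        Similarity is the displacement-pattern distance over the
        landmarks present in ``query``; the query itself is excluded when
        it is part of the cohort (leave-one-out semantics).
        """
        sim = select_similar(query, self.subjects, n=n)
        matrix = self.matrix.select_subjects(sim.selected_ids)
        params = fit_displacement_model(
            matrix, lambda_reg=self.lambda_reg, min_samples=self.min_samples
        )
        return PictorialStructuresResults(self, params, similarity=sim)


class PictorialStructuresResults:
    """Fitted displacement model with prediction and summary methods."""

    def __init__(self, model: PictorialStructuresModel, params: DisplacementModel,
                 similarity=None) -> None:
        self.model = model
        self.params = params
        self.similarity = similarity

    def fuse(self, u: str, known: LandmarkSet) -> FusedGaussian:
        """Closed-form product of the contributor Gaussians for ``u``."""
        return fuse(u, known, self.params)

    def predict(
        self,
        known: LandmarkSet,
        targets: list[str] | tuple[str, ...] = COUINAUD_LANDMARKS,
    ) -> tuple[LandmarkSet, dict[str, str]]:
        """Predict the target landmarks from the present ones."""
        targets = [t for t in targets if not known.is_present(t)]
        return predict_missing(known, self.params, targets)

    def heatmap(self, u: str, known: LandmarkSet, grid=None
                ) -> tuple[ProbabilityMap, list[ProbabilityMap]]:
        """Combined + per-contributor log-probability maps on a grid."""
        return heatmap(u, known, self.params, grid=grid)

    def save(self, path: str | Path) -> None:
        """Write the fitted parameters as a model archive (.npz)."""
        self.params.save(path)

    def pair_frame(self) -> pd.DataFrame:
        """Per-pair parameter table (one row per usable ordered pair)."""
        rows = []
        p = self.params
        for iu, u in enumerate(ALL_LANDMARKS):
            for ik, k in enumerate(ALL_LANDMARKS):
                if not p.usable[iu, ik]:
                    continue
                rows.append(
                    {
                        "u": u,
                        "k": k,
                        "n": int(p.n_samples[iu, ik]),
                        "mu_x": p.mu[iu, ik, 0],
                        "mu_y": p.mu[iu, ik, 1],
                        "mu_z": p.mu[iu, ik, 2],
                        "sigma_trace": float(np.trace(p.sigma[iu, ik])),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        p = self.params
        n_usable = int(p.usable.sum())
        lines = [
            "Pictorial structures displacement model",
            "=" * 47,
            f"Training subjects:      {p.n_samples.max():d} (max per pair)",
            f"Landmarks:              {len(ALL_LANDMARKS)}",
            f"Usable ordered pairs:   {n_usable} / {len(ALL_LANDMARKS) * (len(ALL_LANDMARKS) - 1)}",
            f"Regularization lambda:  {p.regularization:g} mm^2",
            f"Min samples per pair:   {p.min_samples}",
        ]
        if self.similarity is not None:
            lines.append(
                f"Personalized subset:    {self.similarity.subset_size} cases "
                f"(query {self.similarity.query_id})"
            )
        lines.append("-" * 47)
        lines.append(f"{'landmark':<14}{'usable pairs':>14}{'mean sd (mm)':>16}")
        for iu, name in enumerate(ALL_LANDMARKS):
            usable_k = np.flatnonzero(p.usable[iu])
            if len(usable_k) == 0:
                lines.append(f"{name:<14}{0:>14}{'-':>16}")
                continue
            sds = [
                float(np.sqrt(np.trace(p.sigma[iu, ik]) / 3.0)) for ik in usable_k
            ]
            lines.append(
                f"{name:<14}{len(usable_k):>14}{np.mean(sds):>16.2f}"
            )
        return "\n".join(lines)


def load_results(path: str | Path) -> PictorialStructuresResults:
    """Load a saved model archive as a results object (no training data)."""
    params = DisplacementModel.load(path)
    dummy = PictorialStructuresModel.__new__(PictorialStructuresModel)
    dummy.subjects = []
    dummy.lambda_reg = params.regularization
    dummy.min_samples = params.min_samples
    dummy.matrix = None
    return PictorialStructuresResults(dummy, params)
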