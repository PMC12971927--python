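"""Displacement-pattern patient similarity and personalized models.

A population-average displacement model tends toward an "average person";
patients with atypical anatomy (subtypes, prior surgery, unusual habitus)
are poorly served by it.  The remedy is a personalized model: rank the
training cohort by a displacement-pattern distance computed on the
landmarks known for the query, keep the ``n`` most similar cases, and
refit the displacement model on that subset alone.

The distance between patients A and B over their common present landmark
set (size K') is

    D = (1 / K'^2) * sum_{k1} sum_{k2} | d_B(k1, k2) - d_A(k1, k2) |_1

where d(k1, k2) = l_{k1} - l_{k2} and |.|_1 sums absolute per-axis
components.  D depends only on displacements, so it is exactly invariant
to translating either patient; self pairs contribute zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import (
    DEFAULT_LAMBDA,
    MIN_SAMPLES,
    DisplacementModel,
    build_cohort_matrix,
    fit_displacement_model,
)
from .landmarks import LandmarkSet

logger = logging.getLogger(__name__)

#: Default personalized subset size.
DEFAULT_SUBSET_SIZE = 10


def patient_distance(a: LandmarkSet, b: LandmarkSet, norm: str = "l1") -> float:
    """Displacement-pattern distance between two subjects (mm).

    Landmarks missing in either subject are excluded; the double sum runs
    over ordered pairs of the K' common landmarks and is normalised by
    K'^2.  ``norm`` selects the per-pair vector norm: "l1" (componentwise
    absolute differences, the default) or "l2" (Euclidean).
    """
    common = a.present & b.present
    k = int(common.sum())
    if k < 2:
        raise ValueError(
            f"insufficient common landmarks between {a.subject_id!r} and "
            f"{b.subject_id!r}: {k} (need >= 2)"
        )
    pa = a.coords[common]
    pb = b.coords[common]
    da = pa[:, None, :] - pa[None, :, :]
    db = pb[:, None, :] - pb[None, :, :]
    diff = db - da
    if norm == "l1":
        per_pair = np.abs(diff).sum(axis=-1)
    elif norm == "l2":
        per_pair = np.linalg.norm(diff, axis=-1)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    return float(per_pair.sum() / k**2)


@dataclass
class SimilarityResult:
    """Ranked training cases for one query."""

    query_id: str
    ranked: list[tuple[str, float]]  # (subject_id, distance mm), ascending
    subset_size: int

    @property
    def selected_ids(self) -> list[str]:
        return [sid for sid, _ in self.ranked[: self.subset_size]]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "subject_id": [sid for sid, _ in self.ranked],
                "distance_mm": [d for _, d in self.ranked],
                "rank": np.arange(1, len(self.ranked) + 1),
            }
        )


def select_similar(
    query: LandmarkSet,
    cohort: list[LandmarkSet],
    n: int = DEFAULT_SUBSET_SIZE,
    norm: str = "l1",
) -> SimilarityResult:
    """Rank the cohort by distance to the query and keep the ``n`` nearest.

    The query itself (matched by subject_id) is excluded, so drawing the
    query from the training cohort gives leave-one-out semantics.  Ties
    are broken by lexicographic subject_id.  If fewer than ``n`` cases
    admit a distance, all eligible cases are returned with a warning.
    """
    if n < 1:
        raise ValueError("subset size n must be >= 1")
    entries = []
    for subj in cohort:
        if subj.subject_id == query.subject_id:
            continue
        try:
            d = patient_distance(query, subj, norm=norm)
        except ValueError:
            logger.warning(
                "skipping %s: no common landmarks with query %s",
                subj.subject_id, query.subject_id,
            )
            continue
        entries.append((subj.subject_id, d))
    if not entries:
        raise ValueError(
            f"no eligible training case for query {query.subject_id!r}"
        )
    entries.sort(key=lambda e: (e[1], e[0]))
    if len(entries) < n:
        logger.warning(
            "only %d eligible cases for query %s (requested %d)",
            len(entries), query.subject_id, n,
        )
    return SimilarityResult(
        query_id=query.subject_id,
        ranked=entries,
        subset_size=min(n, len(entries)),
    )


def personalized_model(
    query: LandmarkSet,
    cohort: list[LandmarkSet],
    n: int = DEFAULT_SUBSET_SIZE,
    lambda_reg: float = DEFAULT_LAMBDA,
    min_samples: int = MIN_SAMPLES,
    norm: str = "l1",
) -> tuple[DisplacementModel, SimilarityResult]:
    """Fit a displacement model on the ``n`` cases most similar to the query.

    Identical to the base fit except for the training subset.
    """
    sim = select_similar(query, cohort, n=n, norm=norm)
    selected_ids = set(sim.selected_ids)
    selected = [s for s in cohort if s.subject_id in selected_ids]
    matrix = build_cohort_matrix(selected)
    model = fit_displacement_model(matrix, lambda_reg=lambda_reg, min_samples=min_samples)
    return model, sim
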