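"""Leave-one-out evaluation of landmark prediction and segment volumes.

The cohort displacement matrix makes leave-one-out cross-validation
cheap: removing one subject's slice of the P x N x N x 3 matrix and
refitting is identical to fitting on the remaining P-1 subjects.  For
each held-out case the Couinaud landmarks are predicted from the case's
auxiliary landmarks (base model: all remaining subjects; personalized:
the n most similar remaining subjects), and Euclidean errors in mm are
recorded per landmark.

Volume errors compare predicted and reference Couinaud partitions of the
same liver mask as absolute differences in percent of whole-liver volume;
the robustness summary is the fraction of cases with at least one segment
above a volume-error threshold (10% in surgical practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import (
    DEFAULT_LAMBDA,
    MIN_SAMPLES,
    build_cohort_matrix,
    fit_displacement_model,
)
from .inference import predict_missing
from .landmarks import AUXILIARY_LANDMARKS, COUINAUD_LANDMARKS, LandmarkSet
from .personalize import select_similar

logger = logging.getLogger(__name__)


@dataclass
class ErrorReport:
    """Per-landmark and per-segment errors over an evaluated cohort."""

    per_landmark: dict[str, list[float]] = field(default_factory=dict)
    per_segment: dict[str, list[float]] = field(default_factory=dict)
    skipped: dict[str, list[str]] = field(default_factory=dict)  # landmark -> case ids
    case_ids: list[str] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    def mean_errors(self) -> dict[str, float]:
        return {
            k: float(np.mean(v)) for k, v in self.per_landmark.items() if v
        }

    def max_errors(self) -> dict[str, float]:
        return {
            k: float(np.max(v)) for k, v in self.per_landmark.items() if v
        }

    def landmark_frame(self) -> pd.DataFrame:
        rows = []
        for name, errs in self.per_landmark.items():
            for e in errs:
                rows.append({"landmark": name, "error_mm": e})
        return pd.DataFrame(rows)


def loocv(
    cohort: list[LandmarkSet],
    mode: str = "base",
    n_subset: int = 10,
    lambda_reg: float = DEFAULT_LAMBDA,
    min_samples: int = MIN_SAMPLES,
    targets: tuple[str, ...] = COUINAUD_LANDMARKS,
    known_names: tuple[str, ...] = AUXILIARY_LANDMARKS,
) -> ErrorReport:
    """Leave-one-out landmark prediction errors over a cohort.

    For each case the model is fitted on the other P-1 subjects (``mode
    = "base"``) or on the ``n_subset`` most similar of them (``mode =
    "personalized"``, similarity computed on the case's known landmarks),
    the targets are predicted from the case's known landmarks, and
    Euclidean errors against the case's true positions are recorded.
    Targets missing in a case, or unpredictable ones, are logged as
    skipped.
    """
    if len(cohort) < 5:
        raise ValueError("LOOCV needs a cohort of at least 5 subjects")
    if mode not in {"base", "personalized"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "personalized" and n_subset >= len(cohort):
        logger.warning(
            "personalized subset size %d >= cohort size %d; falling back to base",
            n_subset, len(cohort),
        )
        mode = "base"

    full_matrix = build_cohort_matrix(cohort)
    report = ErrorReport(
        per_landmark={t: [] for t in targets},
        skipped={},
        settings={
            "mode": mode,
            "n_subset": n_subset,
            "lambda_reg": lambda_reg,
            "min_samples": min_samples,
            "n_cohort": len(cohort),
        },
    )
    for case in cohort:
        known = case.subset(list(known_names))
        if known.n_present == 0:
            for t in targets:
                report.skipped.setdefault(t, []).append(case.subject_id)
            continue
        if mode == "base":
            matrix = full_matrix.without_subject(case.subject_id)
        else:
            sim = select_similar(known, cohort, n=n_subset)
            matrix = full_matrix.select_subjects(sim.selected_ids)
        model = fit_displacement_model(
            matrix, lambda_reg=lambda_reg, min_samples=min_samples
        )
        predicted, provenance = predict_missing(known, model, list(targets))
        report.case_ids.append(case.subject_id)
        for t in targets:
            if provenance.get(t) != "predicted" or not case.is_present(t):
                report.skipped.setdefault(t, []).append(case.subject_id)
                continue
            err = float(np.linalg.norm(predicted[t] - case[t]))
            report.per_landmark[t].append(err)
    return report


def volume_error_report(pred_labels, true_labels) -> dict[str, float]:
    """Absolute per-segment volume differences in percent of liver volume.

    Both maps must live on the same voxel grid; the metric is symmetric
    in its arguments.
    """
    if pred_labels.labels.labels.shape != true_labels.labels.labels.shape or not np.allclose(
        pred_labels.labels.affine, true_labels.labels.affine
    ):
        raise ValueError("segment label maps are on different grids")
    segments = set(pred_labels.volumes_pct) | set(true_labels.volumes_pct)
    return {
        s: abs(
            pred_labels.volumes_pct.get(s, 0.0) - true_labels.volumes_pct.get(s, 0.0)
        )
        for s in sorted(segments)
    }


def fraction_over_threshold(
    per_case_segment_errors: list[dict[str, float]], threshold_pct: float = 10.0
) -> float:
    """Fraction of cases with >= 1 segment volume error above the threshold."""
    if not per_case_segment_errors:
        return 0.0
    n_over = sum(
        1
        for case in per_case_segment_errors
        if any(e > threshold_pct for e in case.values())
    )
    return n_over / len(per_case_segment_errors)


def subset_size_sweep(
    cohort: list[LandmarkSet],
    sizes: list[int],
    lambda_reg: float = DEFAULT_LAMBDA,
    targets: tuple[str, ...] = COUINAUD_LANDMARKS,
) -> pd.DataFrame:
    """Personalized LOOCV at each subset size; mean and max error per
    landmark per size (one row per size x landmark)."""
    for size in sizes:
        if size < 2 or size > len(cohort):
            raise ValueError(f"subset size {size} outside [2, {len(cohort)}]")
    rows = []
    for size in sizes:
        report = loocv(
            cohort, mode="personalized", n_subset=size, lambda_reg=lambda_reg,
            targets=targets,
        )
        means = report.mean_errors()
        maxes = report.max_errors()
        for t in targets:
            rows.append(
                {
                    "subset_size": size,
                    "landmark": t,
                    "mean_error_mm": means.get(t, np.nan),
                    "max_error_mm": maxes.get(t, np.nan),
                    "n_cases": len(report.per_landmark.get(t, [])),
                }
            )
    return pd.DataFrame(rows)


def paired_wilcoxon(errors_a: list[float], errors_b: list[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on per-case errors.

    Pairs with a zero difference are dropped (scipy default); returns 1.0
    when fewer than 2 informative pairs remain.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    if np.count_nonzero(diff) < 2:
        return 1.0
    return float(stats.wilcoxon(a, b).pvalue)


def log_error(errors_mm, offset: float = 1.0) -> np.ndarray:
    """Natural log of (error + offset mm); plotting transform for skewed
    error distributions with zeros."""
    return np.log(np.asarray(errors_mm, dtype=float) + offset)
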