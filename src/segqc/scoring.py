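"""Observer-anchored calibration of metric scores and the composite rQS.

Each of the 12 metric cells gets its own linear map to a 0-100 score,
fixed by two anchor points: the metric's ideal value maps to 100 and the
second-observer cohort mean maps to the anchor score (85 by default).
Cell scores are clipped to [0, 100] before averaging into the composite
reference quality score (rQS).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .metrics import METRICS, MetricPanel
from .regions import REGIONS

__all__ = ["IDEAL_VALUES", "ScoreCalibration", "QualityScore", "fit_calibration", "score_panel"]

#: ideal (perfect-segmentation) value per metric
IDEAL_VALUES = {"DSC": 1.0, "aRVD": 0.0, "HD95": 0.0, "ASD": 0.0}


@dataclass(frozen=True)
class ScoreCalibration:
    """Per-cell linear metric-to-score maps fitted on an observer cohort.

    ``slopes``/``intercepts`` are keyed by (region, metric); each line passes
    through (ideal value, 100) and (cohort mean, anchor). Slopes are positive
    for DSC and negative for the error-type metrics by construction.
    """

    slopes: dict[tuple[str, str], float]
    intercepts: dict[tuple[str, str], float]
    anchor: float
    cohort_size: int
    cohort_means: dict[tuple[str, str], float]

    def cell_score(self, region: str, metric: str, value: float) -> float:
        raw = self.slopes[(region, metric)] * value + self.intercepts[(region, metric)]
        return float(np.clip(raw, 0.0, 100.0))

    def to_json(self, path: str) -> None:
        payload = {
            "anchor": self.anchor,
            "cohort_size": self.cohort_size,
            "cells": [
                {
                    "region": r,
                    "metric": m,
                    "slope": self.slopes[(r, m)],
                    "intercept": self.intercepts[(r, m)],
                    "cohort_mean": self.cohort_means[(r, m)],
                }
                for r in REGIONS
                for m in METRICS
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "ScoreCalibration":
        with open(path) as fh:
            payload = json.load(fh)
        slopes, intercepts, means = {}, {}, {}
        for cell in payload["cells"]:
            key = (cell["region"], cell["metric"])
            slopes[key] = cell["slope"]
            intercepts[key] = cell["intercept"]
            means[key] = cell["cohort_mean"]
        return cls(slopes, intercepts, payload["anchor"], payload["cohort_size"], means)


@dataclass(frozen=True)
class QualityScore:
    """Composite 0-100 quality score and its 12 per-cell scores."""

    value: float
    cell_scores: dict[tuple[str, str], float]


def fit_calibration(
    cohort_panels: list[MetricPanel], anchor: float = 85.0
) -> ScoreCalibration:
    """Fit the 12 per-cell linear score maps from a second-observer cohort.

    For each cell the line passes through (ideal metric value, 100) and
    (cohort mean of that cell, ``anchor``). A cohort whose mean equals the
    ideal value for some cell leaves that line underdetermined and is
    rejected.
    """
    if len(cohort_panels) < 2:
        raise ValueError("calibration needs a cohort of at least 2 cases")
    for i, p in enumerate(cohort_panels):
        if not p.is_fully_valid:
            raise ValueError(f"cohort panel {i} has invalid cells; cannot calibrate")
    slopes, intercepts, means = {}, {}, {}
    for r in REGIONS:
        for m in METRICS:
            vals = [p.values[(r, m)] for p in cohort_panels]
            mean = float(np.mean(vals))
            ideal = IDEAL_VALUES[m]
            if mean == ideal:
                raise ValueError(
                    f"cohort mean for cell {r}_{m} equals the ideal value "
                    f"({ideal}); the score line is underdetermined"
                )
            slope = (anchor - 100.0) / (mean - ideal)
            slopes[(r, m)] = slope
            intercepts[(r, m)] = 100.0 - slope * ideal
            means[(r, m)] = mean
    return ScoreCalibration(slopes, intercepts, anchor, len(cohort_panels), means)


def score_panel(panel: MetricPanel, calibration: ScoreCalibration) -> QualityScore:
    """Map a metric panel to its composite quality score.

    Each cell is mapped by its calibrated line and clipped to [0, 100];
    invalid cells receive the floor score 0 (the conservative choice for a
    quality-control system). The composite score is the mean of the 12 cell
    scores.
    """
    cell_scores: dict[tuple[str, str], float] = {}
    for r in REGIONS:
        for m in METRICS:
            if panel.valid[(r, m)]:
                cell_scores[(r, m)] = calibration.cell_score(r, m, panel.values[(r, m)])
            else:
                cell_scores[(r, m)] = 0.0
    value = float(np.mean(list(cell_scores.values())))
    return QualityScore(value, cell_scores)
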