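"""High-level analysis pipelines: seizure-feature detectability modelling
and false-detection reporting.

These wire the univariate screen, collinearity filter, backward stepwise
deletion and AUC comparison into the per-threshold analysis a performance
audit reports, and shape the outputs like the standard audit tables (an
odds-ratio table per threshold; a false-detection category table with one
row per threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fd import fd_table, patient_concentration, threshold_dropoff
from .glmm import FixedEffect, compare_model_auc
from .model_selection import (
    StepwiseResult,
    UnivariateResult,
    backward_stepwise,
    collinearity_filter,
    screen_table,
    univariate_screen,
)
from .records import FD_CATEGORIES, FalseDetectionRecord, RecordMeta

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FEATURES",
    "DetectabilityResult",
    "detectability_analysis",
    "FdAnalysisResult",
    "fd_analysis",
    "records_summary",
]

#: The scored seizure features entering the detectability models.
DEFAULT_FEATURES: tuple[str, ...] = (
    "peak_amplitude",
    "rhythmicity",
    "background_score",
    "morphology_onset",
    "morphology_peak",
    "duration",
    "frequency_variability",
    "morphology_change",
    "n_channels_onset",
    "n_channels_peak",
)

#: Fixed coding of the visual scores: ordinal scores enter as categorical
#: terms with the least-rhythmic / normal / rhythmic-delta level as the
#: reference.
FEATURE_CODING: dict[str, FixedEffect] = {
    "rhythmicity": FixedEffect("rhythmicity", categorical=True, reference=1),
    "background_score": FixedEffect("background_score", categorical=True, reference=1),
    "morphology_onset": FixedEffect("morphology_onset", categorical=True, reference="RDD"),
    "morphology_peak": FixedEffect("morphology_peak", categorical=True, reference="RDD"),
}


def _code_features(features, data: pd.DataFrame) -> list[FixedEffect]:
    coded = []
    for f in features:
        if isinstance(f, FixedEffect):
            coded.append(f)
        elif f in FEATURE_CODING:
            coded.append(FEATURE_CODING[f])
        else:
            coded.append(FixedEffect.infer(f, data))
    return coded


@dataclass
class DetectabilityResult:
    """Per-threshold output of the detectability pipeline."""

    threshold: float
    univariate: list[UnivariateResult]
    candidates: list[str]
    collinearity_drops: list[dict]
    stepwise: StepwiseResult
    auc: tuple[float, float, float]
    best_univariate_feature: str | None
    auc_comparison_p: float | None

    def univariate_table(self) -> pd.DataFrame:
        return screen_table(self.univariate)

    def multivariate_table(self) -> pd.DataFrame:
        return self.stepwise.fit.summary_frame()


def detectability_analysis(
    data: pd.DataFrame,
    threshold: float,
    features=DEFAULT_FEATURES,
    group: str = "baby_id",
    outcome_col: str | None = None,
    alpha: float = 0.05,
    collinearity_threshold: float = 0.8,
    n_quad: int = 15,
) -> DetectabilityResult:
    """Run the full detectability analysis at one sensitivity threshold.

    ``outcome_col`` defaults to ``detected_{threshold}``. Steps: univariate
    screen -> significant candidates -> collinearity filter (keep the
    higher-AUC member of each collinear pair) -> backward stepwise
    deletion -> AUC of the final model, compared with the best univariate
    model by the DeLong paired test.
    """
    outcome_col = outcome_col or f"detected_{threshold}"
    if outcome_col not in data.columns:
        raise KeyError(f"outcome column {outcome_col!r} not in data")
    work = data.copy()
    work[outcome_col] = work[outcome_col].astype(float)
    features = [f for f in features if (f.name if isinstance(f, FixedEffect) else f) in work.columns]
    effects = _code_features(features, work)

    uni = univariate_screen(effects, work, outcome_col, group, alpha=alpha, n_quad=n_quad)
    aucs = {r.feature: r.auc for r in uni if np.isfinite(r.auc)}
    significant = [r.feature for r in uni if r.significant]
    candidates, drops = collinearity_filter(
        significant, work, aucs, threshold=collinearity_threshold
    )
    coded = {e.name: e for e in effects}
    if candidates:
        step = backward_stepwise(
            [coded[c] for c in candidates], work, outcome_col, group,
            alpha=alpha, n_quad=n_quad,
        )
    else:
        step = backward_stepwise(effects[:1], work, outcome_col, group, alpha=1.01, n_quad=n_quad)
        step = StepwiseResult(step.fit, [], [], intercept_only=True)

    try:
        auc = step.fit.auc()
    except ValueError:
        auc = (float("nan"), float("nan"), float("nan"))

    best_feature, comparison_p = None, None
    finite = {f: a for f, a in aucs.items() if np.isfinite(a)}
    if finite and not step.intercept_only:
        best_feature = max(finite, key=finite.get)
        best_fit = next(r.fit for r in uni if r.feature == best_feature)
        if best_fit is not None:
            _, comparison_p = compare_model_auc(step.fit, best_fit)
    return DetectabilityResult(
        threshold=threshold,
        univariate=uni,
        candidates=candidates,
        collinearity_drops=drops,
        stepwise=step,
        auc=auc,
        best_univariate_feature=best_feature,
        auc_comparison_p=comparison_p,
    )


@dataclass
class FdAnalysisResult:
    """False-detection report across thresholds."""

    category_table: pd.DataFrame          # audit-style wide table
    dropoff: pd.DataFrame                 # per-category retention ratios
    per_patient: pd.DataFrame             # counts per patient x category x threshold
    concentrations: pd.DataFrame          # top-patient share per category


def fd_analysis(
    records_by_threshold: dict[float, list[FalseDetectionRecord]],
) -> FdAnalysisResult:
    """Aggregate labelled false detections into the audit report tables."""
    if not records_by_threshold:
        raise ValueError("no false-detection lists supplied")
    table = fd_table(records_by_threshold, decimals=None)

    counts_by_threshold = {
        t: {
            cat: sum(r.category == cat for r in recs)
            for cat in FD_CATEGORIES
        }
        for t, recs in records_by_threshold.items()
    }
    dropoff = (
        threshold_dropoff(counts_by_threshold)
        if len(counts_by_threshold) >= 2
        else pd.DataFrame()
    )

    per_patient_rows = []
    conc_rows = []
    for t, recs in sorted(records_by_threshold.items()):
        counted: dict[tuple[str, str], int] = {}
        for r in recs:
            key = (r.event.record_id, r.category)
            counted[key] = counted.get(key, 0) + 1
        for (patient, cat), n in sorted(counted.items()):
            per_patient_rows.append(
                {"threshold": t, "patient": patient, "category": cat, "count": n}
            )
        for cat in FD_CATEGORIES:
            if any(r.category == cat for r in recs):
                top, n, share = patient_concentration(recs, cat)
                conc_rows.append(
                    {
                        "threshold": t,
                        "category": cat,
                        "top_patient": top,
                        "top_count": n,
                        "share_percent": share,
                    }
                )
    return FdAnalysisResult(
        category_table=table,
        dropoff=dropoff,
        per_patient=pd.DataFrame(per_patient_rows),
        concentrations=pd.DataFrame(conc_rows),
    )


def records_summary(records: list[RecordMeta]) -> pd.DataFrame:
    """Cohort metadata summary: records, babies, total and mean duration,
    split by seizure group."""
    frame = pd.DataFrame(
        [
            {
                "record_id": r.record_id,
                "baby_id": r.baby_id,
                "duration_hours": r.duration_hours,
                "group": r.group,
            }
            for r in records
        ]
    )
    rows = []
    for name, sub in [("all", frame)] + [
        (g, frame[frame["group"] == g]) for g in sorted(frame["group"].unique())
    ]:
        rows.append(
            {
                "group": name,
                "n_records": len(sub),
                "n_babies": sub["baby_id"].nunique(),
                "total_hours": sub["duration_hours"].sum(),
                "mean_hours": sub["duration_hours"].mean(),
            }
        )
    return pd.DataFrame(rows)
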