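"""False-detection taxonomy: category shares, per-patient concentration,
threshold drop-off and group comparison.

Every false detection carries one artefact category from a closed
vocabulary (respiration, ECG/pulse, chewing/sucking, bad electrode,
movement/handling, electronic equipment, sweat, unclassified, no artefact);
where no artefact was visible, a background subcategory describes the EEG
(normal, highly rhythmic, sharp waves, low amplitude). Category labels are
manual/imported expert labels — no automated artefact classifier here.

Percentage conventions follow the standard audit-table layout: category
percentages are of the total false detections at that threshold; the
no-artefact background breakdown is expressed as percentages of the
no-artefact count.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glmm import mann_whitney
from .records import FD_CATEGORIES, NO_ARTEFACT_SUBCATEGORIES, FalseDetectionRecord

__all__ = [
    "aggregate_fd",
    "fd_table",
    "patient_concentration",
    "threshold_dropoff",
    "compare_groups_fd",
]


def aggregate_fd(
    records: Sequence[FalseDetectionRecord], threshold: float
) -> pd.DataFrame:
    """Count and share of each false-detection category at one threshold.

    All records must carry the stated threshold. Returns one row per
    category (including zero-count categories) with columns ``count`` and
    ``percent`` (share of all false detections), followed by one row per
    no-artefact background subcategory with ``percent`` expressed relative
    to the no-artefact count. Percentages are NaN when their denominator
    is zero.
    """
    for r in records:
        if abs(r.event.threshold - threshold) > 1e-9:
            raise ValueError(
                f"record at threshold {r.event.threshold} in an aggregation "
                f"for threshold {threshold}"
            )
    counts = {c: 0 for c in FD_CATEGORIES}
    sub_counts = {s: 0 for s in NO_ARTEFACT_SUBCATEGORIES}
    for r in records:
        counts[r.category] += 1
        if r.category == "no_artefact":
            sub_counts[r.background_subcategory] += 1

    total = len(records)
    n_no_artefact = counts["no_artefact"]
    rows = []
    for cat in FD_CATEGORIES:
        rows.append(
            {
                "threshold": threshold,
                "category": cat,
                "subcategory": "",
                "count": counts[cat],
                "percent": 100.0 * counts[cat] / total if total else float("nan"),
            }
        )
    for sub in NO_ARTEFACT_SUBCATEGORIES:
        rows.append(
            {
                "threshold": threshold,
                "category": "no_artefact",
                "subcategory": sub,
                "count": sub_counts[sub],
                "percent": 100.0 * sub_counts[sub] / n_no_artefact
                if n_no_artefact
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def fd_table(
    records_by_threshold: Mapping[float, Sequence[FalseDetectionRecord]],
    decimals: int | None = 1,
) -> pd.DataFrame:
    """Audit-style wide table: one row per threshold, one ``<category>`` and
    ``<category>_pct`` column pair per category (plus the no-artefact
    background breakdown). ``decimals=None`` keeps full precision."""
    rows = []
    for threshold in sorted(records_by_threshold):
        agg = aggregate_fd(records_by_threshold[threshold], threshold)
        row: dict = {"threshold": threshold}
        for _, r in agg.iterrows():
            key = r["category"] if not r["subcategory"] else f"no_artefact_{r['subcategory']}"
            pct = r["percent"]
            row[key] = r["count"]
            row[f"{key}_pct"] = (
                round(pct, decimals) if decimals is not None and np.isfinite(pct) else pct
            )
        rows.append(row)
    return pd.DataFrame(rows)


def patient_concentration(
    records: Sequence[FalseDetectionRecord], category: str
) -> tuple[str, int, float]:
    """The patient contributing most false detections of ``category`` and
    that patient's share of the category total.

    Returns ``(record_id, count, share_percent)``. Undefined (raises) when
    the category has no false detections. Ties break towards the
    lexicographically smallest record id.
    """
    if category not in FD_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    in_cat = [r for r in records if r.category == category]
    if not in_cat:
        raise ValueError(f"no false detections in category {category!r}")
    counts: dict[str, int] = {}
    for r in in_cat:
        counts[r.event.record_id] = counts.get(r.event.record_id, 0) + 1
    top = max(sorted(counts), key=counts.get)
    share = 100.0 * counts[top] / len(in_cat)
    return top, counts[top], share


def threshold_dropoff(
    counts_by_threshold: Mapping[float, Mapping[str, int]]
) -> pd.DataFrame:
    """Per-category retention of false detections as the threshold rises.

    ``counts_by_threshold`` maps each threshold (>= 2 required, compared in
    ascending order) to per-category counts. Retention at threshold t is
    count(t) / count(t_min) where t_min is the most sensitive (lowest)
    threshold; categories with a zero baseline get NaN retention and are
    flagged in the ``baseline_zero`` column.
    """
    thresholds = sorted(counts_by_threshold)
    if len(thresholds) < 2:
        raise ValueError("need counts for at least 2 thresholds")
    base = counts_by_threshold[thresholds[0]]
    categories = sorted({c for t in thresholds for c in counts_by_threshold[t]})
    rows = []
    for cat in categories:
        baseline = base.get(cat, 0)
        for t in thresholds:
            count = counts_by_threshold[t].get(cat, 0)
            rows.append(
                {
                    "category": cat,
                    "threshold": t,
                    "count": count,
                    "retention": count / baseline if baseline else float("nan"),
                    "baseline_zero": baseline == 0,
                }
            )
    return pd.DataFrame(rows)


def compare_groups_fd(
    rates_seizure_group: Sequence[float],
    rates_nonseizure_group: Sequence[float],
) -> tuple[float, float]:
    """Mann–Whitney U comparison of per-patient false-detection rates
    (FD/hr) between seizure and non-seizure babies. Returns (U, p)."""
    return mann_whitney(rates_seizure_group, rates_nonseizure_group)
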