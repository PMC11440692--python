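"""Group-wise statistics, dataset summaries and the radar table.

Nonparametric tests use mid-rank tie correction (scipy defaults).  P-values
are reported raw; an optional Holm-adjusted column can be requested but is
off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .classification import assign_grade_group

TESTS_TWO_GROUP = ("mann_whitney", "t_test")
TESTS_MULTI_GROUP = ("kruskal_wallis", "one_way_anova")


@dataclass
class GroupComparison:
    metric_name: str
    groups: list[dict]  # label, n, mean, sd, median
    test: str
    statistic: float
    p_value: float


@dataclass
class DatasetSummary:
    n_patients: Optional[int]
    n_images: int
    n_cells: int
    n_instances_total: int
    n_instances_per_grade: dict = field(default_factory=dict)


def _group_values(records: Iterable, metric: str, grouping: str):
    groups: dict = {}
    for rec in records:
        grade = getattr(rec, "grade", None)
        if grade is None:
            continue
        key = grade if grouping == "grade" else assign_grade_group(grade)
        value = getattr(rec, metric, None)
        if value is None:
            continue
        groups.setdefault(key, []).append(float(value))
    return {k: np.asarray(v) for k, v in sorted(groups.items(), key=str)}


def compare_groups(
    records: Iterable,
    metric: str,
    grouping: str = "group",
    test: str = "auto",
) -> GroupComparison:
    """Compare a morphometry metric across grades or LGG/HGG groups.

    ``test`` may be kruskal_wallis, one_way_anova, mann_whitney, t_test or
    "auto" (Kruskal-Wallis for >2 groups, Mann-Whitney for 2).
    """
    groups = _group_values(records, metric, grouping)
    if len(groups) < 2:
        raise ValueError(
            f"need >= 2 non-empty groups for {metric}, got {len(groups)}"
        )
    samples = list(groups.values())
    if test == "auto":
        test = "mann_whitney" if len(samples) == 2 else "kruskal_wallis"
    if test in ("t_test", "one_way_anova") and any(len(s) < 2 for s in samples):
        raise ValueError(f"{test} requires n >= 2 in every group")
    if test in TESTS_TWO_GROUP and len(samples) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(samples)}")
    if test in TESTS_MULTI_GROUP and len(samples) < 2:
        raise ValueError(f"{test} requires >= 2 groups")

    if test == "kruskal_wallis":
        res = sstats.kruskal(*samples)
    elif test == "one_way_anova":
        res = sstats.f_oneway(*samples)
    elif test == "mann_whitney":
        res = sstats.mannwhitneyu(*samples, alternative="two-sided")
    elif test == "t_test":
        res = sstats.ttest_ind(*samples)
    else:
        raise ValueError(f"unknown test {test!r}")

    return GroupComparison(
        metric_name=metric,
        groups=[
            {
                "label": str(label),
                "n": int(len(vals)),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "median": float(np.median(vals)),
            }
            for label, vals in groups.items()
        ],
        test=test,
        statistic=float(res.statistic),
        p_value=float(min(max(res.pvalue, 0.0), 1.0)),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


def summarize_dataset(records: Iterable, summaries: Iterable = (),
                      n_patients: Optional[int] = None) -> DatasetSummary:
    """Counts of images, cells and instances, split per WHO grade.

    Enforces the consistency check Σ per-grade counts = total whenever
    every instance carries a grade (exact integer arithmetic).
    """
    records = list(records)
    summaries = list(summaries)
    per_grade: dict[int, int] = {}
    n_ungraded = 0
    image_ids = set()
    for rec in records:
        image_ids.add(rec.image_id)
        grade = getattr(rec, "grade", None)
        if grade is None:
            n_ungraded += 1
        else:
            per_grade[grade] = per_grade.get(grade, 0) + 1
    total = len(records)
    if n_ungraded == 0 and sum(per_grade.values()) != total:
        raise AssertionError("per-grade counts do not sum to the total")
    for s in summaries:
        image_ids.add(s.image_id)
    return DatasetSummary(
        n_patients=n_patients,
        n_images=len(image_ids),
        n_cells=len(summaries),
        n_instances_total=total,
        n_instances_per_grade=dict(sorted(per_grade.items())),
    )


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """Cohort-table style percentage, rounded half-away-from-zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    value = 100.0 * count / total
    factor = 10**decimals
    return np.floor(value * factor + 0.5) / factor


def radar_summary(
    records: Iterable,
    metrics: Sequence[str] = (
        "area_um2",
        "perimeter_um",
        "circularity",
        "density_per_um2",
        "area_ratio",
    ),
    grouping: str = "group",
) -> pd.DataFrame:
    """Group means per metric, min-max rescaled to [0, 1] across groups.

    A metric whose group means are all equal is rescaled to 0.5 and noted
    in the frame's ``attrs["constant_metrics"]``.
    """
    records = list(records)
    rows: dict[str, dict[str, float]] = {}
    constant = []
    for metric in metrics:
        groups = _group_values(records, metric, grouping)
        if not groups:
            continue
        means = {str(k): float(np.mean(v)) for k, v in groups.items()}
        lo, hi = min(means.values()), max(means.values())
        if hi - lo < 1e-15:
            rows[metric] = {k: 0.5 for k in means}
            constant.append(metric)
        else:
            rows[metric] = {k: (m - lo) / (hi - lo) for k, m in means.items()}
    df = pd.DataFrame(rows).T
    df.attrs["constant_metrics"] = constant
    return df


def comparisons_table(comparisons: Sequence[GroupComparison],
                      holm: bool = False) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        row = {
            "metric": c.metric_name,
            "test": c.test,
            "statistic": c.statistic,
            "p_value": c.p_value,
        }
        for g in c.groups:
            row[f"mean_{g['label']}"] = g["mean"]
            row[f"n_{g['label']}"] = g["n"]
        rows.append(row)
    df = pd.DataFrame(rows)
    if holm and not df.empty:
        df["p_holm"] = holm_adjust(df["p_value"].tolist())
    return df
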