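"""Region-class aggregation, fold changes and unpaired comparisons.

Per-focal-cell metrics are aggregated into region-class summaries at one
of two levels:

* ``per_roi_then_pool`` — average within each ROI first, then average the
  ROI means (each ROI contributes equally regardless of its cell count);
* ``pooled_cells`` — pool every focal cell of the region class (large
  ROIs dominate).

Published neighborhood analyses rarely state which level they use, and
the two differ on unbalanced data, so both are first-class here and the
level is always recorded in the summary.

Group comparisons use the two-sided unpaired t-test; the Welch
(unequal-variance) variant is the default, with the pooled-variance
variant behind a flag.  No multiple-testing correction is applied —
p-values are nominal, as they are in the figure legends this mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from .tissue_io import ROIGeometry

LEVELS = ("per_roi_then_pool", "pooled_cells")


@dataclass
class RegionSummary:
    """Aggregated metrics for one region class.

    ``stats`` is a DataFrame indexed by metric name with columns
    ``mean, sem, n, n_missing`` (``n`` = contributing units at the chosen
    level: ROIs for ``per_roi_then_pool``, cells for ``pooled_cells``).
    """

    region_class: str
    level: str
    n_rois: int
    n_focal_cells: int
    stats: pd.DataFrame

    def mean(self, metric: str) -> float:
        if metric not in self.stats.index:
            raise ConfigurationError(
                f"metric {metric!r} not in summary for {self.region_class!r}"
            )
        return float(self.stats.loc[metric, "mean"])


@dataclass
class FoldChange:
    """Ratio of group means with orientation metadata.

    ``ratio`` = mean(numerator_class) / mean(denominator_class); NaN with
    ``defined=False`` when the denominator mean is 0 or either mean is
    missing.  ``inverse`` carries the opposite orientation so both
    directions are always reported.
    """

    metric: str
    numerator_class: str
    denominator_class: str
    ratio: float
    inverse: float
    defined: bool


def _mean_sem(values: np.ndarray) -> tuple[float, float, int]:
    v = values[~np.isnan(values)]
    n = len(v)
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(np.mean(v))
    sem = float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return mean, sem, n


def summarize_by_region(
    records: pd.DataFrame,
    rois: Mapping[str, ROIGeometry] | None = None,
    *,
    level: str = "per_roi_then_pool",
    metrics: Sequence[str] | None = None,
) -> dict[str, RegionSummary]:
    """Aggregate per-focal-cell records into one summary per region class.

    ``records`` must carry ``roi_id`` plus numeric metric columns; the
    region class is taken from a ``region_class`` column if present,
    otherwise joined from ``rois``.  Missing metric values are excluded
    from means and counted in ``n_missing``.  Region classes present in
    ``rois`` but without focal cells yield a summary with missing means.
    """
    if level not in LEVELS:
        raise ConfigurationError(f"level must be one of {LEVELS}")
    records = records.copy()
    if "region_class" not in records.columns:
        if rois is None:
            raise ConfigurationError(
                "records have no region_class column and no ROI table was given"
            )
        mapping = {rid: roi.region_class for rid, roi in rois.items()}
        unknown = set(records["roi_id"].unique()) - set(mapping)
        if unknown:
            raise ConfigurationError(f"records reference ROIs without metadata: {sorted(unknown)}")
        records["region_class"] = records["roi_id"].map(mapping)
    if metrics is None:
        skip = {"cell_id", "roi_id", "region_class", "phenotype", "n_neighbors", "empty_neighborhood"}
        metrics = [
            c
            for c in records.columns
            if c not in skip and pd.api.types.is_numeric_dtype(records[c])
        ]

    summaries: dict[str, RegionSummary] = {}
    classes = list(pd.unique(records["region_class"]))
    if rois is not None:
        for roi in rois.values():
            if roi.region_class not in classes:
                classes.append(roi.region_class)
    for cls in classes:
        grp = records[records["region_class"] == cls]
        rows = {}
        for m in metrics:
            vals = grp[m].to_numpy(dtype=float) if len(grp) else np.array([])
            n_missing = int(np.isnan(vals).sum())
            if level == "pooled_cells":
                mean, sem, n = _mean_sem(vals)
            else:
                roi_means = (
                    grp.groupby("roi_id")[m].mean().to_numpy(dtype=float)
                    if len(grp)
                    else np.array([])
                )
                mean, sem, n = _mean_sem(roi_means)
            rows[m] = {"mean": mean, "sem": sem, "n": n, "n_missing": n_missing}
        summaries[cls] = RegionSummary(
            region_class=cls,
            level=level,
            n_rois=int(grp["roi_id"].nunique()) if len(grp) else 0,
            n_focal_cells=int(len(grp)),
            stats=pd.DataFrame.from_dict(rows, orient="index"),
        )
    return summaries


def fold_change(summary_a: RegionSummary, summary_b: RegionSummary, metric: str) -> FoldChange:
    """Ratio of group means a/b for one metric, with both orientations.

    Satisfies ``fold_change(a, b).ratio * fold_change(b, a).ratio == 1``
    whenever both are defined.
    """
    ma, mb = summary_a.mean(metric), summary_b.mean(metric)
    if np.isnan(ma) or np.isnan(mb) or mb == 0:
        return FoldChange(metric, summary_a.region_class, summary_b.region_class,
                          float("nan"), float("nan"), False)
    return FoldChange(
        metric=metric,
        numerator_class=summary_a.region_class,
        denominator_class=summary_b.region_class,
        ratio=ma / mb,
        inverse=mb / ma if ma != 0 else float("nan"),
        defined=True,
    )


@dataclass
class TTestOutcome:
    statistic: float
    df: float
    pvalue: float
    variant: str


def unpaired_t(group_a, group_b, variant: str = "welch") -> TTestOutcome:
    """Two-sided unpaired t-test between two samples.

    ``variant='welch'`` (default) uses the unequal-variance form;
    ``'pooled'`` the classical pooled-variance form.  Symmetric up to the
    sign of t under group swap.

    Raises
    ------
    InsufficientDataError
        Either group has fewer than 2 values.
    DegenerateDataError
        Both groups have zero variance (the statistic is 0/0).
    """
    if variant not in ("welch", "pooled"):
        raise ConfigurationError("variant must be 'welch' or 'pooled'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise DegenerateDataError("both groups have zero variance; t is undefined")
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestOutcome(float(res.statistic), float(res.df), float(res.pvalue), variant)


def region_report(
    summaries: Mapping[str, RegionSummary],
    records: pd.DataFrame,
    *,
    reference_class: str,
    variant: str = "welch",
) -> pd.DataFrame:
    """Flat report table: one row per (region class, metric).

    Columns: ``region_class, metric, mean, sem, n, fold_vs_reference,
    p_nominal``.  Fold changes and nominal p-values (unpaired t on the
    units of the summary level) compare each class against
    ``reference_class``; the reference rows carry fold 1 and p NaN.
    """
    if reference_class not in summaries:
        raise ConfigurationError(f"reference class {reference_class!r} not summarized")
    ref = summaries[reference_class]
    level = ref.level

    def _unit_values(cls: str, metric: str) -> np.ndarray:
        grp = records[records["region_class"] == cls]
        if level == "pooled_cells":
            return grp[metric].to_numpy(dtype=float)
        return grp.groupby("roi_id")[metric].mean().to_numpy(dtype=float)

    rows = []
    for cls, summ in summaries.items():
        for metric in summ.stats.index:
            fc = fold_change(summ, ref, metric)
            p = float("nan")
            if cls != reference_class:
                va = _unit_values(cls, metric)
                vb = _unit_values(reference_class, metric)
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                if len(va) >= 2 and len(vb) >= 2 and (np.var(va, ddof=1) > 0 or np.var(vb, ddof=1) > 0):
                    p = unpaired_t(va, vb, variant=variant).pvalue
            rows.append(
                {
                    "region_class": cls,
                    "metric": metric,
                    "mean": summ.stats.loc[metric, "mean"],
                    "sem": summ.stats.loc[metric, "sem"],
                    "n": summ.stats.loc[metric, "n"],
                    "fold_vs_reference": fc.ratio if cls != reference_class else 1.0,
                    "p_nominal": p,
                }
            )
    return pd.DataFrame(rows)
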