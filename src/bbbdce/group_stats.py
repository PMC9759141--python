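"""Genotype group comparison of ROI K-trans metrics.

Per ROI and per metric (normalized peak height, peak position, or ROI mean
K-trans) the two groups are compared with a one-way analysis of covariance
using the ROI voxel count as covariate — larger regions yield smoother
histograms, so size must be partialled out. Outliers are first removed per
group with a ROUT-style robust FDR procedure, and the standardized effect
size is Cohen's d computed from the two groups' means and SDs with the
unweighted pooled SD

    d = |m_a - m_b| / sqrt((s_a^2 + s_b^2) / 2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncovaResult",
    "GroupComparison",
    "rout_outliers",
    "cohens_d",
    "ancova_genotype",
    "summarize_table",
    "directional_summary",
]

logger = logging.getLogger(__name__)

#: Quantile of |residuals| estimating one robust SD (the Gaussian 68.27 %
#: point), as used by robust-regression outlier removal.
_RSDR_PERCENTILE: float = 68.27


@dataclass(frozen=True)
class AncovaResult:
    """Group-term F test and covariate-adjusted group means."""

    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    adjusted_means: dict[str, float]


@dataclass
class GroupComparison:
    """One ROI x metric comparison row of the summary table."""

    roi_id: int
    roi_name: str
    metric: str
    n_a: int
    mean_a: float
    sd_a: float
    n_b: int
    mean_b: float
    sd_b: float
    ancova_f: float
    ancova_p: float
    cohens_d: float
    mean_diff_signed: float  # mean_b - mean_a (direction retained)
    outliers_removed: list[str] = field(default_factory=list)


def rout_outliers(
    values: np.ndarray, q_pct: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Robust FDR-based outlier removal (ROUT-style) on a 1-D sample.

    A robust location (median) and scale (the 68.27th percentile of absolute
    residuals, inflated by n/(n-1) for the fitted location) define
    studentized residuals; two-sided t-tail probabilities (df = n-1) are
    screened by a Benjamini-Hochberg step-up at Q = ``q_pct`` percent, and
    flagged points are removed. With fewer than 3 values nothing is removed
    (a warning is logged).

    Returns ``(kept_values, removed_indices)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if q_pct <= 0 or q_pct >= 100:
        raise ValueError("q_pct must lie in (0, 100)")
    if n < 3:
        if n > 0:
            logger.warning("rout_outliers: n=%d < 3, no removal attempted", n)
        return values.copy(), np.array([], dtype=int)
    resid = values - np.median(values)
    rsdr = np.percentile(np.abs(resid), _RSDR_PERCENTILE) * n / (n - 1)
    if rsdr == 0:
        # Degenerate spread: any distinct point is infinitely extreme.
        removed = np.flatnonzero(resid != 0)
        kept = np.delete(values, removed)
        return kept, removed
    t_res = resid / rsdr
    p = 2.0 * stats.t.sf(np.abs(t_res), df=n - 1)
    order = np.argsort(p)
    q = q_pct / 100.0
    thresh = q * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    k = np.flatnonzero(below).max() + 1 if below.any() else 0
    removed = np.sort(order[:k])
    kept = np.delete(values, removed)
    return kept, removed


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Unsigned Cohen's d with the unweighted root-mean-square pooled SD.

    d = |mean_a - mean_b| / sqrt((sd_a^2 + sd_b^2)/2). Note this pooling does
    not weight by group size. Raises if both SDs are zero while the means
    differ (d undefined); equal means with zero spread give d = 0.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    pooled = np.sqrt((sd_a**2 + sd_b**2) / 2.0)
    diff = abs(mean_a - mean_b)
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise ValueError(
            f"Cohen's d undefined: both SDs are zero but means differ "
            f"({mean_a} vs {mean_b})"
        )
    return float(diff / pooled)


def ancova_genotype(
    metric: np.ndarray,
    group: np.ndarray,
    covariate: np.ndarray,
) -> AncovaResult:
    """One-way ANCOVA of a metric on group with one covariate.

    Fits ``metric ~ intercept + group + covariate`` by OLS; the group effect
    is tested with the single-df partial F (equal to the squared t of the
    group coefficient, i.e. the type-III test here). Adjusted means are
    evaluated at the grand covariate mean. A constant covariate degrades to
    one-way ANOVA with a warning; a covariate perfectly collinear with the
    grouping is rejected.
    """
    import statsmodels.api as sm

    y = np.asarray(metric, dtype=float).ravel()
    group = np.asarray(group).ravel()
    cov = np.asarray(covariate, dtype=float).ravel()
    if not (y.size == group.size == cov.size):
        raise ValueError("metric, group and covariate must have equal length")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.tolist()}")
    g = (group == levels[1]).astype(float)
    n_a, n_b = int((g == 0).sum()), int((g == 1).sum())
    if min(n_a, n_b) < 2:
        raise ValueError("each group needs at least 2 subjects")

    cov_centered = cov - cov.mean()
    use_cov = np.ptp(cov_centered) > 0
    if not use_cov:
        warnings.warn(
            "covariate is constant; ANCOVA reduces to one-way ANOVA",
            UserWarning,
            stacklevel=2,
        )
        design = np.column_stack([np.ones_like(y), g])
    else:
        design = np.column_stack([np.ones_like(y), g, cov_centered])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                "covariate is perfectly collinear with the grouping; "
                "ANCOVA design is singular"
            )
    fit = sm.OLS(y, design).fit()
    t_g = fit.tvalues[1]
    f_stat = float(t_g**2)
    p = float(fit.pvalues[1])
    if not np.isfinite(p):
        raise ValueError("ANCOVA failed: non-finite p-value (degenerate data)")
    adj = {
        str(levels[0]): float(fit.params[0]),
        str(levels[1]): float(fit.params[0] + fit.params[1]),
    }
    return AncovaResult(
        f_stat=f_stat,
        p_value=min(p, 1.0),
        df_num=1,
        df_den=int(fit.df_resid),
        adjusted_means=adj,
    )


def _group_block(
    sub: pd.DataFrame, metric: str, q_pct: float
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Apply outlier removal to one group's metric; returns kept rows."""
    vals = sub[metric].to_numpy(dtype=float)
    kept, removed = rout_outliers(vals, q_pct=q_pct)
    removed_ids = sub["subject_id"].to_numpy()[removed].tolist()
    keep_mask = np.ones(vals.size, dtype=bool)
    keep_mask[removed] = False
    return kept, sub["voxel_count"].to_numpy(dtype=float)[keep_mask], removed_ids


def summarize_table(
    metrics: pd.DataFrame,
    q_pct: float = 1.0,
    metric_names: tuple[str, ...] = ("peak_height", "peak_position"),
) -> pd.DataFrame:
    """Per-ROI group comparison table (one row per ROI x metric).

    ``metrics`` is the long-format per-subject table with columns
    subject_id, group, roi_id, roi_name, voxel_count and the metric columns.
    For each ROI and metric, outliers are removed per group (ROUT at
    Q = ``q_pct``%), then the ANCOVA (voxel-count covariate) and Cohen's d
    are computed from the retained subjects. Missing or degenerate ROIs are
    reported as rows with NaN statistics and the run continues.
    """
    required = {"subject_id", "group", "roi_id", "roi_name", "voxel_count"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    groups = np.sort(metrics["group"].unique())
    if groups.size != 2:
        raise ValueError(f"expected 2 groups in metrics table, got {groups.tolist()}")
    ga, gb = groups

    rows: list[GroupComparison] = []
    for roi_id, roi_df in metrics.groupby("roi_id", sort=True):
        roi_name = str(roi_df["roi_name"].iloc[0])
        for metric in metric_names:
            if metric not in roi_df.columns:
                logger.warning("ROI %s: metric %s missing, row skipped", roi_name, metric)
                continue
            sub_a = roi_df[roi_df["group"] == ga]
            sub_b = roi_df[roi_df["group"] == gb]
            try:
                vals_a, cov_a, rem_a = _group_block(sub_a, metric, q_pct)
                vals_b, cov_b, rem_b = _group_block(sub_b, metric, q_pct)
                if min(vals_a.size, vals_b.size) < 2:
                    raise ValueError("fewer than 2 subjects per group after removal")
                anc = ancova_genotype(
                    np.concatenate([vals_a, vals_b]),
                    np.array([ga] * vals_a.size + [gb] * vals_b.size),
                    np.concatenate([cov_a, cov_b]),
                )
                d = cohens_d(
                    vals_a.mean(), vals_a.std(ddof=1), vals_b.mean(), vals_b.std(ddof=1)
                )
                rows.append(
                    GroupComparison(
                        roi_id=int(roi_id),
                        roi_name=roi_name,
                        metric=metric,
                        n_a=int(vals_a.size),
                        mean_a=float(vals_a.mean()),
                        sd_a=float(vals_a.std(ddof=1)),
                        n_b=int(vals_b.size),
                        mean_b=float(vals_b.mean()),
                        sd_b=float(vals_b.std(ddof=1)),
                        ancova_f=anc.f_stat,
                        ancova_p=anc.p_value,
                        cohens_d=d,
                        mean_diff_signed=float(vals_b.mean() - vals_a.mean()),
                        outliers_removed=rem_a + rem_b,
                    )
                )
            except (ValueError, KeyError) as exc:
                logger.warning("ROI %s metric %s: %s", roi_name, metric, exc)
                rows.append(
                    GroupComparison(
                        roi_id=int(roi_id), roi_name=roi_name, metric=metric,
                        n_a=len(sub_a), mean_a=np.nan, sd_a=np.nan,
                        n_b=len(sub_b), mean_b=np.nan, sd_b=np.nan,
                        ancova_f=np.nan, ancova_p=np.nan, cohens_d=np.nan,
                        mean_diff_signed=np.nan,
                    )
                )
    table = pd.DataFrame([vars(r) for r in rows])
    table["outliers_removed"] = table["outliers_removed"].apply(
        lambda ids: ";".join(ids)
    )
    return table


def directional_summary(metrics: pd.DataFrame) -> dict:
    """Count ROIs where the group-B mean ROI K-trans exceeds group-A's.

    Uses the raw (pre-outlier-removal) ``roi_mean_ktrans`` column; the count
    over the ten regions summarises the direction of any diffuse group
    difference (a null cohort is binomial around 5/10).
    """
    if "roi_mean_ktrans" not in metrics.columns:
        raise ValueError("metrics table lacks the roi_mean_ktrans column")
    groups = np.sort(metrics["group"].unique())
    if groups.size != 2:
        raise ValueError("expected 2 groups")
    ga, gb = groups
    per_roi = (
        metrics.groupby(["roi_id", "group"])["roi_mean_ktrans"].mean().unstack("group")
    )
    higher = per_roi[gb] > per_roi[ga]
    return {
        "group_a": str(ga),
        "group_b": str(gb),
        "n_rois": int(len(per_roi)),
        "n_group_b_higher": int(higher.sum()),
        "rois_group_b_higher": [int(r) for r in per_roi.index[higher]],
    }
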