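"""Model validation procedures.

Three evaluations mirror how a normative database earns trust:

* **calibration** — Z-scores of held-out normative subjects should follow
  N(0, 1) (mean ~0, variance ~1 per component and pooled);
* **effectiveness** — Z-scores from two normative models that differ in
  age-regression method (continuous spline vs sliding-window age bands)
  should correlate strongly on the same subjects if both capture the same
  normal-state trends;
* **accuracy** — under a true between-sex offset, a sex-stratified model
  should standardize an injected anomaly at least as far from zero as a
  pooled (sex-agnostic) model in the affected cells.

Plus the sex-difference decision tree used to justify stratification:
Student's t when both groups pass Shapiro-Wilk normality and Levene's
variance-equality gates, Welch's t when only normality holds, Mann-Whitney
U otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SexDifferenceResult",
    "sex_difference_test",
    "sex_difference_map",
    "cross_model_correlation",
    "calibration_report",
    "anomaly_contrast",
]


@dataclass(frozen=True)
class SexDifferenceResult:
    """One cell of a group-difference analysis, with auditable gate p-values."""

    test_used: str  # "student-t" | "welch-t" | "mann-whitney-u"
    statistic: float
    p_value: float
    normality_p_a: float
    normality_p_b: float
    variance_equality_p: Optional[float]
    alpha: float
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def sex_difference_test(x, y, alpha: float = 0.05, gate_alpha: float = 0.05) -> SexDifferenceResult:
    """Two-group comparison routed by the normality/variance decision tree.

    Both groups pass Shapiro-Wilk (at *gate_alpha*) and Levene's test ->
    Student's t; normality holds but variances differ -> Welch's t;
    normality fails in either group -> Mann-Whitney U.  Constant (zero
    variance) groups go to Mann-Whitney with a note, since the parametric
    gates are undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return SexDifferenceResult(
            "mann-whitney-u", float(stat), float(p), np.nan, np.nan, None, alpha,
            note="constant group; parametric gates undefined",
        )
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x < gate_alpha or sw_y < gate_alpha:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return SexDifferenceResult(
            "mann-whitney-u", float(stat), float(p), float(sw_x), float(sw_y), None, alpha
        )
    lev_p = stats.levene(x, y).pvalue
    if lev_p < gate_alpha:
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        return SexDifferenceResult(
            "welch-t", float(stat), float(p), float(sw_x), float(sw_y), float(lev_p), alpha
        )
    stat, p = stats.ttest_ind(x, y, equal_var=True)
    return SexDifferenceResult(
        "student-t", float(stat), float(p), float(sw_x), float(sw_y), float(lev_p), alpha
    )


def sex_difference_map(features: pd.DataFrame, group_col: str = "sex",
                       threshold: float = 0.1, gate_alpha: float = 0.05) -> pd.DataFrame:
    """Per-region group-difference map.

    *features*: one row per subject, *group_col* with exactly two levels,
    every other numeric column a region/feature.  Returns one row per
    region with the routed test, p-value, and ``significant`` mask at the
    display threshold (default p <= 0.1).
    """
    levels = sorted(features[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col!r} must have exactly 2 levels, got {levels}")
    a = features[features[group_col] == levels[0]]
    b = features[features[group_col] == levels[1]]
    rows = []
    for col in features.columns:
        if col == group_col or not pd.api.types.is_numeric_dtype(features[col]):
            continue
        res = sex_difference_test(a[col].dropna(), b[col].dropna(), alpha=threshold,
                                  gate_alpha=gate_alpha)
        rows.append(
            {
                "region": col,
                "test_used": res.test_used,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "significant": res.p_value <= threshold,
            }
        )
    return pd.DataFrame(rows)


def _align_zscores(z1: pd.DataFrame, z2: pd.DataFrame) -> pd.DataFrame:
    keys = ["subject_id", "channel", "band"]
    a = z1.set_index(keys)["z"]
    b = z2.set_index(keys)["z"]
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            "z-score tables are keyed differently; "
            f"missing from second: {list(only_a[:5])}, missing from first: {list(only_b[:5])}"
        )
    return pd.DataFrame({"z1": a, "z2": b.loc[a.index]}).reset_index()


def cross_model_correlation(z1: pd.DataFrame, z2: pd.DataFrame, by: str = "overall"):
    """Pearson correlation between two Z-score tables on identical keys.

    ``by="overall"`` returns a single r over all matched cells;
    ``by="band"`` returns a Series of r per band plus an ``"overall"``
    entry.  Rows where either z is undefined are dropped pairwise.
    """
    merged = _align_zscores(z1, z2)
    merged = merged[np.isfinite(merged["z1"]) & np.isfinite(merged["z2"])]
    if by == "overall":
        return float(stats.pearsonr(merged["z1"], merged["z2"]).statistic)
    if by == "band":
        out = {
            band: float(stats.pearsonr(g["z1"], g["z2"]).statistic)
            for band, g in merged.groupby("band", observed=True)
        }
        out["overall"] = float(stats.pearsonr(merged["z1"], merged["z2"]).statistic)
        return pd.Series(out)
    raise ValueError("by must be 'overall' or 'band'")


def calibration_report(z: pd.DataFrame, grouping=("channel", "band")) -> dict:
    """Sample mean and variance of Z-scores, per group and pooled.

    Undefined cells are excluded, with their count reported.  For a
    well-calibrated normative model on held-out normative subjects the
    pooled mean is ~0 and the pooled variance ~1.
    """
    finite = z[np.isfinite(z["z"])]
    n_excluded = len(z) - len(finite)
    grouped = finite.groupby(list(grouping), observed=True)["z"].agg(["mean", "var", "count"])
    return {
        "pooled_mean": float(finite["z"].mean()),
        "pooled_var": float(finite["z"].var(ddof=1)),
        "n": int(len(finite)),
        "n_excluded": n_excluded,
        "per_group": grouped,
    }


def anomaly_contrast(subjects, stratified, pooled) -> pd.DataFrame:
    """Z-score anomalous subjects under sex-stratified vs pooled models.

    *subjects* is a list of (anomalous) :class:`~qeegnorm.synthetic.Subject`
    whose sex matches the stratified model.  Both models must be trained on
    the same cohort (checked via their training-data hash when available,
    since the contrast is only meaningful on a shared reference
    population).  Returns one row per (subject, channel, band) with
    ``z_stratified``, ``z_pooled``, ``abs_diff`` and an ``affected`` mask
    from each subject's anomaly spec.
    """
    s_hash = getattr(stratified, "cohort_hash_", None)
    p_hash = getattr(pooled, "cohort_hash_", None)
    if s_hash is None or p_hash is None:
        warnings.warn("models carry no cohort hash; cannot verify shared cohort")
    elif s_hash != p_hash:
        raise ValueError(
            "stratified and pooled models were trained on different cohorts; "
            "the contrast is only meaningful on a shared reference population"
        )
    from .synthetic import Cohort  # local import to avoid cycle at module load

    cohort = Cohort(subjects=list(subjects), config=None)
    bp = cohort.band_power_table()
    demo = cohort.demographics()
    z_s = stratified.zscore(bp, demo).set_index(["subject_id", "channel", "band"])["z"]
    z_p = pooled.zscore(bp, demo).set_index(["subject_id", "channel", "band"])["z"]
    out = pd.DataFrame({"z_stratified": z_s, "z_pooled": z_p.loc[z_s.index]})
    out["abs_diff"] = out["z_stratified"].abs() - out["z_pooled"].abs()
    affected = pd.Series(False, index=out.index)
    for s in subjects:
        if s.anomaly_spec is not None:
            band, channels, _ = s.anomaly_spec
            for ch in channels:
                affected.loc[(s.id, ch, band)] = True
    out["affected"] = affected
    return out.reset_index()
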