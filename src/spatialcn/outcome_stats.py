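"""Outcome association statistics for per-patient spatial summaries.

Kaplan–Meier estimation and two-group log-rank tests (lifelines), two-sample
and paired t-tests, one-way ANOVA with Bonferroni-adjusted pairwise
comparisons, and Pearson correlation (scipy.stats), plus the cohort-level
association suite: CN frequency and per-CN cell counts vs survival under a
high/low median split, CN-frequency vs proximity correlations, and the
spatial-score group comparison. Survival times are in months; event = 1
marks an observed death, 0 a censored follow-up. p < 0.05 is starred with
the usual *, **, *** tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GroupingRule",
    "km_estimate",
    "km_median",
    "logrank_test",
    "dichotomize",
    "compare_groups",
    "pearson_correlation",
    "significance_stars",
    "run_association_suite",
]


@dataclass(frozen=True)
class GroupingRule:
    """How to split patients on a continuous covariate.

    kind: "median_split" (<= median -> low, > median -> high; ties low),
    "threshold" (with `value`), or "short_long_term" (survival time
    < 12 months vs > 24 months, intermediate patients dropped).
    """

    kind: str = "median_split"
    value: float | None = None
    short_months: float = 12.0
    long_months: float = 24.0

    def __post_init__(self) -> None:
        if self.kind not in ("median_split", "threshold", "short_long_term"):
            raise ValueError(f"unknown grouping rule {self.kind!r}")
        if self.kind == "threshold" and self.value is None:
            raise ValueError("threshold rule requires a value")


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"time_months", "event"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"survival records lack columns: {sorted(missing)}")
    t = records["time_months"].to_numpy(float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise ValueError("survival times must be finite and positive")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table with columns time_months and survival; S(0) = 1 and
    the estimate drops only at observed event times.
    """
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], records["event"])
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time_months": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def km_median(records: pd.DataFrame) -> float:
    """Median survival time (months); inf if the curve never reaches 0.5."""
    records = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(records["time_months"], records["event"])
    return float(kmf.median_survival_time_)


def logrank_test(records: pd.DataFrame, groups: pd.Series) -> dict:
    """Two-group log-rank test; chi-square statistic with 1 df.

    `groups` is aligned to `records` (same length / index) and must take
    exactly two values. Identical groups give statistic 0, p = 1. A
    degenerate comparison with no events yields statistic 0 with a warning.
    """
    records = _check_records(records)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {len(levels)}")
    a = records.loc[g == levels[0]]
    b = records.loc[g == levels[1]]
    if a["event"].sum() == 0 and b["event"].sum() == 0:
        logger.warning("log-rank with zero events in both groups; statistic set to 0")
        return {"statistic": 0.0, "p_value": 1.0, "groups": tuple(levels)}
    res = _ll_logrank(
        a["time_months"], b["time_months"], event_observed_A=a["event"], event_observed_B=b["event"]
    )
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        logger.warning("degenerate log-rank comparison; statistic set to 0")
        return {"statistic": 0.0, "p_value": 1.0, "groups": tuple(levels)}
    return {"statistic": stat, "p_value": float(res.p_value), "groups": tuple(levels)}


def dichotomize(values: pd.Series, rule: GroupingRule) -> pd.Series:
    """Label patients "low"/"high" (or "short"/"long") per the rule.

    median_split: <= median -> "low", > median -> "high" (ties to low).
    threshold: same with the supplied cutoff. short_long_term: survival
    < short_months -> "short", > long_months -> "long", others dropped.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 patients to dichotomize")
    v = values.astype(float)
    if rule.kind == "median_split":
        cut = float(v.median())
        if (v == v.iloc[0]).all():
            raise ValueError("all values identical; no median split exists")
        return pd.Series(np.where(v <= cut, "low", "high"), index=values.index, name="group")
    if rule.kind == "threshold":
        return pd.Series(
            np.where(v <= float(rule.value), "low", "high"), index=values.index, name="group"
        )
    # short_long_term on survival times in months
    lab = np.where(
        v < rule.short_months, "short", np.where(v > rule.long_months, "long", None)
    )
    out = pd.Series(lab, index=values.index, name="group")
    return out.dropna()


def compare_groups(samples: list[np.ndarray], design: str = "two_sample_t") -> pd.DataFrame:
    """Two-sample t, paired t, or one-way ANOVA + Bonferroni pairwise t.

    Returns one row per comparison with statistic, p_value and (for the
    ANOVA design) p_adjusted = min(1, n_comparisons * p). Zero variance in
    every group with equal means is reported as statistic 0, p = 1.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if design == "two_sample_t":
        if len(samples) != 2:
            raise ValueError("two_sample_t needs exactly 2 samples")
        return pd.DataFrame([_safe_ttest(samples[0], samples[1], paired=False)])
    if design == "paired_t":
        if len(samples) != 2 or len(samples[0]) != len(samples[1]):
            raise ValueError("paired_t needs 2 samples of equal length")
        return pd.DataFrame([_safe_ttest(samples[0], samples[1], paired=True)])
    if design == "anova_bonferroni":
        if len(samples) < 3:
            raise ValueError("ANOVA design needs >= 3 groups")
        rows = []
        f, p = stats.f_oneway(*samples)
        rows.append(
            {"comparison": "anova", "statistic": float(f), "p_value": float(p), "p_adjusted": float(p)}
        )
        pairs = [(i, j) for i in range(len(samples)) for j in range(i + 1, len(samples))]
        m = len(pairs)
        for i, j in pairs:
            r = _safe_ttest(samples[i], samples[j], paired=False)
            r["comparison"] = f"group{i}_vs_group{j}"
            r["p_adjusted"] = min(1.0, m * r["p_value"])
            rows.append(r)
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design {design!r}")


def _safe_ttest(a: np.ndarray, b: np.ndarray, paired: bool) -> dict:
    # degenerate variance: equal means -> no evidence (p = 1); a constant
    # nonzero difference is certain (p = 0)
    if paired:
        diff = a - b
        degenerate = np.ptp(diff) == 0
        delta = float(diff.mean()) if len(diff) else 0.0
    else:
        degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
        delta = float(a.mean() - b.mean())
    if degenerate:
        logger.warning("zero within-group variance; p set by mean difference")
        if delta == 0:
            return {"comparison": "t", "statistic": 0.0, "p_value": 1.0}
        return {"comparison": "t", "statistic": float(np.sign(delta) * np.inf), "p_value": 0.0}
    if paired:
        t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return {"comparison": "t", "statistic": float(t), "p_value": float(p)}


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson r with the t-transform p-value (n - 2 df).

    Zero variance in either vector leaves r undefined (NaN, logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance; Pearson r undefined")
        return {"r": float("nan"), "p_value": float("nan"), "n": len(x)}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n": len(x)}


def significance_stars(p: float) -> str:
    """The usual tiers: * p<0.05, ** p<0.01, *** p<0.001; 'ns' otherwise."""
    if not np.isfinite(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _km_groups(merged: pd.DataFrame, values: pd.Series, label: str) -> dict | None:
    """Median-split survival comparison on one covariate; None if unsplittable."""
    common = merged.index.intersection(values.dropna().index)
    if len(common) < 4:
        return None
    v = values.loc[common]
    try:
        groups = dichotomize(v, GroupingRule("median_split"))
    except ValueError:
        return None
    rec = merged.loc[common]
    res = logrank_test(rec, groups.loc[common])
    med = {
        g: km_median(rec.loc[groups == g]) for g in ("low", "high")
    }
    return {
        "test": "logrank_median_split",
        "covariate": label,
        "statistic": res["statistic"],
        "p_value": res["p_value"],
        "stars": significance_stars(res["p_value"]),
        "median_low": med["low"],
        "median_high": med["high"],
        "n": len(common),
    }


def run_association_suite(
    cn_freq: pd.DataFrame,
    survival: pd.DataFrame,
    cn_cell_counts: pd.DataFrame | None = None,
    distance_covariates: pd.DataFrame | None = None,
    spatial_score: pd.Series | None = None,
    risk_cn: str | None = None,
) -> pd.DataFrame:
    """Cohort-level association report.

    Inputs are patient-indexed: cn_freq (patients x CN frequency columns),
    the survival table, optional per-(type, CN) cell counts, optional mean
    nearest-distance covariates (columns correlated against risk-CN
    frequency), and an optional per-patient spatial score compared between
    high/low risk-CN-frequency groups. Patients missing from either side of
    a comparison are inner-joined away (logged).
    """
    surv = _check_records(survival).set_index("patient_id")
    common = cn_freq.index.intersection(surv.index)
    dropped = len(cn_freq.index.union(surv.index)) - len(common)
    if dropped:
        logger.info("association suite: %d patients excluded by inner join", dropped)
    merged = surv.loc[common]
    rows: list[dict] = []

    for cn in cn_freq.columns:
        row = _km_groups(merged, cn_freq.loc[common, cn], f"freq[{cn}]")
        if row:
            rows.append(row)

    if cn_cell_counts is not None:
        for col in cn_cell_counts.columns:
            row = _km_groups(merged, cn_cell_counts[col], f"count[{col}]")
            if row:
                rows.append(row)

    if distance_covariates is not None and risk_cn is not None:
        freq = cn_freq.loc[common, risk_cn]
        for col in distance_covariates.columns:
            pair = pd.concat([freq, distance_covariates[col]], axis=1, join="inner").dropna()
            if len(pair) >= 3:
                res = pearson_correlation(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
                rows.append(
                    {
                        "test": "pearson",
                        "covariate": f"freq[{risk_cn}]_vs_{col}",
                        "statistic": res["r"],
                        "p_value": res["p_value"],
                        "stars": significance_stars(res["p_value"]),
                        "n": res["n"],
                    }
                )

    if spatial_score is not None and risk_cn is not None:
        freq = cn_freq[risk_cn]
        both = freq.index.intersection(spatial_score.dropna().index)
        if len(both) >= 4:
            groups = dichotomize(freq.loc[both], GroupingRule("median_split"))
            lo = spatial_score.loc[both][groups == "low"].to_numpy()
            hi = spatial_score.loc[both][groups == "high"].to_numpy()
            t = compare_groups([hi, lo], "two_sample_t").iloc[0]
            rows.append(
                {
                    "test": "two_sample_t",
                    "covariate": f"spatial_score_by_freq[{risk_cn}]",
                    "statistic": float(t["statistic"]),
                    "p_value": float(t["p_value"]),
                    "stars": significance_stars(float(t["p_value"])),
                    "mean_low": float(np.mean(lo)) if len(lo) else float("nan"),
                    "mean_high": float(np.mean(hi)) if len(hi) else float("nan"),
                    "n": len(both),
                }
            )

    return pd.DataFrame(rows)
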