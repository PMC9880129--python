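"""Registration impact assessment: motion grading, deltas, paired statistics.

Subjective motion is scored on a numerical ranking scale (NRS, 0 = no
motion .. 10 = nondiagnostic) and mapped to four clinical motion categories
(0 none, 1 mild, 2 moderate, 3 severe).  Objective impact is the change —
postregistration minus preregistration, negative meaning motion reduction —
in voxel-wise Tofts residual percentiles and in Ktrans summaries over the
lesion ROI.  Paired nonparametric statistics (sign test, Wilcoxon
signed-rank, Spearman rank correlation, Kruskal-Wallis for subgroups)
mirror the analysis such validation studies report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .perfusion import ToftsFitResult

__all__ = ["MotionScore", "CaseAssessment", "nrs_to_category",
           "delta_assessment", "paired_tests", "group_comparison",
           "compile_report"]

#: Exact-enumeration Wilcoxon up to this sample size (no ties/zeros).
WILCOXON_EXACT_MAX_N = 25

# NRS -> motion category: 0 -> 0 (none); 1-3 -> 1 (mild);
# 4-7 -> 2 (moderate); 8-10 -> 3 (severe / nondiagnostic).
_CATEGORY_EDGES = ((0, 0, 0), (1, 3, 1), (4, 7, 2), (8, 10, 3))


def nrs_to_category(nrs) -> int:
    """Motion category (0-3) for an integer NRS value (0-10)."""
    if isinstance(nrs, (bool, np.bool_)):
        raise ValueError("NRS must be an integer, not a bool")
    if isinstance(nrs, float) and not float(nrs).is_integer():
        raise ValueError(f"NRS must be an integer, got {nrs}")
    n = int(nrs)
    for lo, hi, cat in _CATEGORY_EDGES:
        if lo <= n <= hi:
            return cat
    raise ValueError(f"NRS must lie in 0..10, got {nrs}")


@dataclass
class MotionScore:
    """An NRS reading with its derived motion category."""

    nrs: int
    category: int = field(init=False)

    def __post_init__(self) -> None:
        self.category = nrs_to_category(self.nrs)


@dataclass
class CaseAssessment:
    """Pre/post registration comparison for one case (negative = better)."""

    case_id: str
    percentiles: np.ndarray
    pre_residual_percentiles: np.ndarray
    post_residual_percentiles: np.ndarray
    delta_residual_percentiles: np.ndarray
    pre_ktrans_mean: float
    post_ktrans_mean: float
    delta_ktrans_mean: float
    pre_ktrans_sd: float
    post_ktrans_sd: float
    delta_ktrans_sd: float
    nrs_pre: int | None = None
    nrs_post: int | None = None
    runtime_s: float = float("nan")

    @property
    def category_pre(self):
        return None if self.nrs_pre is None else nrs_to_category(self.nrs_pre)

    @property
    def category_post(self):
        return None if self.nrs_post is None else nrs_to_category(self.nrs_post)


def delta_assessment(pre: ToftsFitResult, post: ToftsFitResult,
                     percentiles=None, case_id: str = "case",
                     nrs_pre: int | None = None, nrs_post: int | None = None,
                     runtime_s: float = float("nan")) -> CaseAssessment:
    """Post-minus-pre residual percentile and Ktrans deltas on a shared ROI."""
    if pre.roi_mask is None or post.roi_mask is None \
            or not np.array_equal(pre.roi_mask, post.roi_mask):
        raise ValueError("pre and post fits must share the same ROI voxels")
    pct = np.asarray(percentiles if percentiles is not None
                     else np.arange(10, 91, 10), dtype=float)
    rp_pre = np.asarray(pre.residual_percentiles(pct), dtype=float)
    rp_post = np.asarray(post.residual_percentiles(pct), dtype=float)
    return CaseAssessment(
        case_id=case_id,
        percentiles=pct,
        pre_residual_percentiles=rp_pre,
        post_residual_percentiles=rp_post,
        delta_residual_percentiles=rp_post - rp_pre,
        pre_ktrans_mean=pre.ktrans_mean,
        post_ktrans_mean=post.ktrans_mean,
        delta_ktrans_mean=post.ktrans_mean - pre.ktrans_mean,
        pre_ktrans_sd=pre.ktrans_sd,
        post_ktrans_sd=post.ktrans_sd,
        delta_ktrans_sd=post.ktrans_sd - pre.ktrans_sd,
        nrs_pre=nrs_pre, nrs_post=nrs_post, runtime_s=runtime_s)


def paired_tests(pre, post) -> dict:
    """Sign test, Wilcoxon signed-rank and Spearman rho(pre, delta).

    Sign test: exact binomial on the sign of (post - pre), ties dropped.
    Wilcoxon: exact enumeration for n <= 25 without ties/zeros, otherwise
    normal approximation with tie correction.  All two-sided.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be equal-length 1D samples")
    if pre.size < 5:
        raise ValueError("need at least 5 pairs")
    delta = post - pre
    nonzero = delta[delta != 0]
    out: dict = {"n": int(pre.size), "n_nonzero": int(nonzero.size)}
    if nonzero.size == 0:
        out["sign_test_p"] = float("nan")
        out["sign_test_note"] = "all pairs tied; sign test undefined"
        out["wilcoxon_p"] = float("nan")
    else:
        n_pos = int(np.sum(nonzero > 0))
        out["sign_test_p"] = float(stats.binomtest(
            n_pos, nonzero.size, 0.5, alternative="two-sided").pvalue)
        ranks_tied = (np.unique(np.abs(nonzero)).size < nonzero.size)
        if nonzero.size <= WILCOXON_EXACT_MAX_N and not ranks_tied:
            method = "exact"
        else:
            method = "approx"
        res = stats.wilcoxon(nonzero, alternative="two-sided",
                             method=method, correction=False)
        out["wilcoxon_p"] = float(res.pvalue)
        out["wilcoxon_method"] = method
    if np.ptp(pre) == 0 or np.ptp(delta) == 0:
        out["spearman_rho"] = float("nan")  # rank correlation undefined
        out["spearman_p"] = float("nan")
    else:
        rho = stats.spearmanr(pre, delta)
        out["spearman_rho"] = float(rho.statistic)
        out["spearman_p"] = float(rho.pvalue)
    return out


def group_comparison(values, labels) -> float:
    """Kruskal-Wallis p-value (nonparametric one-way ANOVA) across groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == lab] for lab in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return 1.0  # identical groups: H = 0 by construction
    return float(stats.kruskal(*groups).pvalue)


def compile_report(cases) -> pd.DataFrame:
    """One row per case plus a ``summary`` row (medians, IQRs, p-values).

    Deterministic column order; re-parsing a written CSV reproduces the
    values.  IQR uses the same linear-interpolation quartile convention as
    the residual percentiles.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("need at least one case")
    rows = []
    for c in cases:
        row = {
            "case_id": c.case_id,
            "nrs_pre": c.nrs_pre, "nrs_post": c.nrs_post,
            "category_pre": c.category_pre, "category_post": c.category_post,
            "pre_ktrans_mean": c.pre_ktrans_mean,
            "post_ktrans_mean": c.post_ktrans_mean,
            "delta_ktrans_mean": c.delta_ktrans_mean,
            "pre_ktrans_sd": c.pre_ktrans_sd,
            "post_ktrans_sd": c.post_ktrans_sd,
            "delta_ktrans_sd": c.delta_ktrans_sd,
            "runtime_s": c.runtime_s,
        }
        for p, d in zip(c.percentiles, c.delta_residual_percentiles):
            row[f"delta_residual_p{int(p):02d}"] = d
        rows.append(row)
    df = pd.DataFrame(rows)
    numeric = [c for c in df.columns if c != "case_id"]
    summary = {"case_id": "summary"}
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summary[col] = med
            summary[f"{col}_iqr"] = q3 - q1
    if len(cases) >= 5:
        pre = np.array([c.pre_ktrans_mean for c in cases])
        post = np.array([c.post_ktrans_mean for c in cases])
        tests = paired_tests(pre, post)
        summary["ktrans_sign_test_p"] = tests["sign_test_p"]
        summary["ktrans_wilcoxon_p"] = tests["wilcoxon_p"]
    out = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    lead = ["case_id", "nrs_pre", "nrs_post", "category_pre", "category_post"]
    rest = sorted(c for c in out.columns if c not in lead)
    return out[lead + rest]
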