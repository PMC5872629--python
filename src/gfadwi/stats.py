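"""Nonparametric pre/post statistics and the cohort analysis report.

Paired changes are tested with the Wilcoxon signed-rank test (zero
differences discarded, exact two-sided p by sign-pattern enumeration for
small tie-free samples, otherwise a tie- and continuity-corrected normal
approximation — the convention common statistical packages apply).
Associations between change scores use Spearman's rho with the
t-distribution p-value; both rho and R^2 = rho^2 are reported because
clinical papers print either form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable
from .scores import records_from_frame, scores_from_record
from .synthetic import ROI_NAMES

__all__ = [
    "PairedSample",
    "TestResult",
    "CorrelationResult",
    "wilcoxon_signed_rank",
    "spearman",
    "analyze_cohort",
    "CohortReport",
]

#: largest effective n for which the exact null distribution is enumerated
EXACT_N_MAX = 20


@dataclass(frozen=True)
class PairedSample:
    """Complete per-subject (pre, post) pairs for one measure."""

    pre: np.ndarray
    post: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        pre = np.asarray(self.pre, dtype=float)
        post = np.asarray(self.post, dtype=float)
        if pre.shape != post.shape or pre.ndim != 1:
            raise ValueError("pre and post must be 1-D arrays of equal length")
        if pre.shape[0] < 3:
            raise ValueError("paired test requires at least 3 pairs")
        if not (np.all(np.isfinite(pre)) and np.all(np.isfinite(post))):
            raise ValueError("paired sample contains non-finite values")
        object.__setattr__(self, "pre", pre)
        object.__setattr__(self, "post", post)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str  # "exact", "normal-approximation" or "degenerate"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False

    @property
    def r_squared(self) -> float:
        return self.rho * self.rho


def _exact_signed_rank_p(w_min: float, ranks: np.ndarray) -> float:
    """Exact two-sided p by enumerating all sign assignments.

    ``ranks`` must be distinct integers 1..n; the null distribution of
    W+ is built by dynamic programming over rank subsets and the
    two-sided p is 2 * P(W <= w_min), capped at 1.
    """
    n = ranks.shape[0]
    max_sum = int(ranks.sum())
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        # copy on the RHS keeps the recurrence 0/1 (each rank used once)
        counts[r:] = counts[r:] + counts[:-r]
    cdf = counts[: int(w_min) + 1].sum() / 2.0**n
    return min(1.0, 2.0 * cdf)


def wilcoxon_signed_rank(sample: PairedSample) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zero differences are discarded (Wilcoxon's classical rule); |d| are
    ranked with midranks for ties and W = min(W+, W-).  The p-value is
    exact (full enumeration) when the effective n is at most 20 and the
    |d| are tie-free, otherwise a normal approximation with tie
    correction and a 0.5 continuity correction.  All-zero differences
    give the degenerate result p = 1.
    """
    d = sample.post - sample.pre
    d = d[d != 0.0]
    n = d.shape[0]
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n_effective=0, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = np.unique(np.abs(d)).shape[0] < n
    if n <= EXACT_N_MAX and not has_ties:
        p = _exact_signed_rank_p(w, ranks)
        return TestResult(statistic=w, p_value=p, n_effective=n, method="exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:  # every |d| identical and n small: no usable variance
        return TestResult(statistic=w, p_value=1.0, n_effective=n, method="degenerate")
    z = (w - mean + 0.5) / math.sqrt(var)  # W = min(...) <= mean, correct toward it
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return TestResult(statistic=w, p_value=p, n_effective=n, method="normal-approximation")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with two-sided t-distribution p-value.

    rho is the Pearson correlation of midranks; p comes from
    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom.  Zero
    variance in either input yields a degenerate (NaN) result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    n = x.shape[0]
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=p, n=n)


@dataclass
class CohortReport:
    """Machine-readable pre/post analysis of one cohort.

    ``roi_table`` mirrors the published table layout: one row per ROI
    with pre/post mean +/- SD, Wilcoxon p for FA and GFA, and Spearman
    correlations of the GFA change against the FMA and WMFT-lpt changes.
    ``clinical`` summarizes FMA, WMFT mean performance rate and lpt.
    """

    roi_table: pd.DataFrame
    clinical: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "roi_table": self.roi_table.to_dict(orient="records"),
            "clinical": self.clinical.to_dict(orient="records"),
        }


def _subject_scores(table: CohortTable) -> pd.DataFrame:
    rows = [
        {
            "subject": s.subject,
            "timepoint": s.timepoint,
            "fma_total": s.fma_total,
            "wmft_rate": s.wmft_rate,
            "wmft_lpt": s.wmft_lpt,
        }
        for record, fma in records_from_frame(table.scores)
        for s in [scores_from_record(record, fma)]
    ]
    return pd.DataFrame(rows)


def _pivot(df: pd.DataFrame, value: str, index: str = "subject") -> pd.DataFrame:
    wide = df.pivot(index=index, columns="timepoint", values=value)
    missing = {"pre", "post"} - set(wide.columns)
    if missing:
        raise ValueError(f"timepoint(s) {sorted(missing)} missing for {value!r}")
    if wide.isna().any().any():
        raise ValueError(f"unmatched pre/post pairs for {value!r}")
    return wide


def analyze_cohort(table: CohortTable) -> CohortReport:
    """Full pre/post analysis of a cohort table.

    Raises ``ValueError`` naming the first missing ROI or score column.
    """
    present = set(table.rois["roi"].unique())
    for roi in ROI_NAMES:
        if roi not in present:
            raise ValueError(f"cohort table is missing ROI {roi!r}")

    scores = _subject_scores(table)
    fma = _pivot(scores, "fma_total")
    rate = _pivot(scores, "wmft_rate")
    lpt = _pivot(scores, "wmft_lpt")
    d_fma = (fma["post"] - fma["pre"]).sort_index()
    d_lpt = (lpt["post"] - lpt["pre"]).sort_index()

    roi_rows = []
    for roi in ROI_NAMES:
        sub = table.rois[table.rois["roi"] == roi]
        fa = _pivot(sub, "mean_fa")
        gfa = _pivot(sub, "mean_gfa")
        fa_test = wilcoxon_signed_rank(
            PairedSample(fa["pre"].to_numpy(), fa["post"].to_numpy(), measure=f"FA {roi}")
        )
        gfa_test = wilcoxon_signed_rank(
            PairedSample(gfa["pre"].to_numpy(), gfa["post"].to_numpy(), measure=f"GFA {roi}")
        )
        d_gfa = (gfa["post"] - gfa["pre"]).sort_index()
        corr_fma = spearman(d_gfa.to_numpy(), d_fma.loc[d_gfa.index].to_numpy())
        corr_lpt = spearman(d_gfa.to_numpy(), d_lpt.loc[d_gfa.index].to_numpy())
        roi_rows.append(
            {
                "roi": roi,
                "fa_pre_mean": fa["pre"].mean(),
                "fa_pre_sd": fa["pre"].std(ddof=1),
                "fa_post_mean": fa["post"].mean(),
                "fa_post_sd": fa["post"].std(ddof=1),
                "fa_p": fa_test.p_value,
                "gfa_pre_mean": gfa["pre"].mean(),
                "gfa_pre_sd": gfa["pre"].std(ddof=1),
                "gfa_post_mean": gfa["post"].mean(),
                "gfa_post_sd": gfa["post"].std(ddof=1),
                "gfa_p": gfa_test.p_value,
                "rho_gfa_fma": corr_fma.rho,
                "p_gfa_fma": corr_fma.p_value,
                "rho_gfa_lpt": corr_lpt.rho,
                "p_gfa_lpt": corr_lpt.p_value,
                "r2_gfa_lpt": corr_lpt.r_squared,
            }
        )

    clinical_rows = []
    for name, wide in (("fma_total", fma), ("wmft_rate", rate), ("wmft_lpt", lpt)):
        test = wilcoxon_signed_rank(
            PairedSample(wide["pre"].to_numpy(), wide["post"].to_numpy(), measure=name)
        )
        clinical_rows.append(
            {
                "measure": name,
                "pre_mean": wide["pre"].mean(),
                "pre_sd": wide["pre"].std(ddof=1),
                "post_mean": wide["post"].mean(),
                "post_sd": wide["post"].std(ddof=1),
                "p": test.p_value,
            }
        )
    return CohortReport(roi_table=pd.DataFrame(roi_rows), clinical=pd.DataFrame(clinical_rows))
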