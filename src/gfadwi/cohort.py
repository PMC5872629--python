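"""Synthetic pre/post rehabilitation cohorts with planted effects.

The generator emulates a 36-subject single-arm cohort assessed before
and after a 15-day intervention: per-subject ROI-mean FA and GFA in four
motor-area white-matter ROIs, Fugl-Meyer assessment (FMA) totals, and
Wolf Motor Function Test (WMFT) task times.  Defaults reproduce the
published group means and SDs of such a cohort.

Pre and post values of each measure are jointly Gaussian with a
configurable within-subject (test-retest) correlation, so both marginals
match the configured means/SDs.  The change in lesioned-BA4 GFA and the
change in WMFT log performance time (lpt) are additionally coupled
through a Gaussian copula: the underlying Pearson correlation is
calibrated as r = 2*sin(pi*rho/6) so the planted Spearman correlation is
``rho_star`` in expectation, and perfectly monotone pairs result at
``rho_star = +/-1``.  To keep that coupling exact the lpt change is
innovated directly (post = pre + delta), which leaves the post-lpt
marginal SD slightly above its configured value; all other marginals
are exact up to clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .synthetic import ROI_NAMES

__all__ = ["CohortSpec", "CohortTable", "simulate_cohort", "RoiStats"]

N_WMFT_TASKS = 15
WMFT_TIME_CAP = 120.0
_LN_CAP = float(np.log(WMFT_TIME_CAP))


@dataclass(frozen=True)
class RoiStats:
    """Pre/post mean and SD of one metric in one ROI."""

    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float

    def __post_init__(self) -> None:
        if self.pre_sd <= 0 or self.post_sd <= 0:
            raise ValueError("SDs must be positive")


def _default_gfa() -> dict:
    return {
        "BA4_lesioned": RoiStats(0.181, 0.006, 0.186, 0.005),
        "BA4_nonlesioned": RoiStats(0.193, 0.012, 0.200, 0.014),
        "BA6_lesioned": RoiStats(0.165, 0.0002, 0.168, 0.001),
        "BA6_nonlesioned": RoiStats(0.172, 0.007, 0.175, 0.005),
    }


def _default_fa() -> dict:
    return {
        "BA4_lesioned": RoiStats(0.194, 0.023, 0.195, 0.025),
        "BA4_nonlesioned": RoiStats(0.207, 0.018, 0.211, 0.013),
        "BA6_lesioned": RoiStats(0.179, 0.006, 0.181, 0.004),
        "BA6_nonlesioned": RoiStats(0.189, 0.002, 0.190, 0.003),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated pre/post cohort.

    ``rho_star`` is the planted Spearman correlation between the change
    in lesioned-BA4 GFA and the change in WMFT-lpt (negative: subjects
    whose GFA rises most speed up most).  ``retest_rho`` is the
    within-subject pre/post correlation shared by all measures.
    """

    n_subjects: int = 36
    gfa: dict = field(default_factory=_default_gfa)
    fa: dict = field(default_factory=_default_fa)
    rho_star: float = -0.363
    fma: RoiStats = RoiStats(45.4, 12.3, 50.9, 12.0)
    lpt: RoiStats = RoiStats(2.8, 1.2, 2.4, 1.3)
    retest_rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be at least 3")
        if not -1.0 <= self.rho_star <= 1.0:
            raise ValueError("|rho_star| must not exceed 1")
        if not -1.0 < self.retest_rho < 1.0:
            raise ValueError("retest_rho must lie strictly within (-1, 1)")
        for table in (self.gfa, self.fa):
            missing = set(ROI_NAMES) - set(table)
            if missing:
                raise ValueError(f"missing ROI statistics for {sorted(missing)}")


@dataclass
class CohortTable:
    """Per-subject clinical scores and ROI summaries, pre and post.

    ``scores`` has one row per subject x timepoint with columns
    ``subject, timepoint, fma_total, task_01 .. task_15`` (seconds).
    ``rois`` has one row per subject x timepoint x ROI with columns
    ``subject, timepoint, roi, mean_fa, mean_gfa, n_voxels``.
    """

    scores: pd.DataFrame
    rois: pd.DataFrame

    @property
    def subjects(self) -> list:
        return sorted(self.scores["subject"].unique())


def _paired_normal(rng, n, stats: RoiStats, rho: float):
    """Pre/post draws with exact marginals and retest correlation rho.

    Returns (pre, post, z_delta) where z_delta is the standard-normal
    innovation of the change score post - pre.
    """
    a = rng.standard_normal(n)
    b = rng.standard_normal(n)
    w = rho * a + np.sqrt(1.0 - rho * rho) * b
    pre = stats.pre_mean + stats.pre_sd * a
    post = stats.post_mean + stats.post_sd * w
    sd_delta = np.sqrt(
        stats.pre_sd**2 + stats.post_sd**2 - 2.0 * rho * stats.pre_sd * stats.post_sd
    )
    z_delta = (post - pre - (stats.post_mean - stats.pre_mean)) / sd_delta
    return pre, post, z_delta


def simulate_cohort(spec: CohortSpec, seed=None) -> CohortTable:
    """Draw one cohort realization; deterministic under a fixed seed.

    ``seed`` overrides ``spec.seed`` when given.  GFA/FA values are
    clipped to [0, 1]; FMA totals are rounded and clipped to the 0-66
    scale; the 15 WMFT task times are all set to exp(lpt) with lpt
    clipped at ln(120) so the log-mean-time transform reproduces the
    drawn lpt exactly.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    rho = spec.retest_rho
    subjects = [f"S{i + 1:03d}" for i in range(n)]

    roi_rows = []
    z_ba4 = None
    for roi in ROI_NAMES:
        g_pre, g_post, z_delta = _paired_normal(rng, n, spec.gfa[roi], rho)
        f_pre, f_post, _ = _paired_normal(rng, n, spec.fa[roi], rho)
        if roi == "BA4_lesioned":
            z_ba4 = z_delta
        for tp, g, f in (("pre", g_pre, f_pre), ("post", g_post, f_post)):
            roi_rows.append(
                pd.DataFrame(
                    {
                        "subject": subjects,
                        "timepoint": tp,
                        "roi": roi,
                        "mean_fa": np.clip(f, 0.0, 1.0),
                        "mean_gfa": np.clip(g, 0.0, 1.0),
                        "n_voxels": 60,
                    }
                )
            )
    rois = pd.concat(roi_rows, ignore_index=True)

    # Gaussian-copula coupling of delta(lpt) to delta(GFA, lesioned BA4):
    # the latent change normals carry Pearson r = 2*sin(pi*rho*/6), which
    # gives Spearman rho_star in expectation and perfectly monotone pairs
    # at rho_star = +/-1.  The lpt change is innovated directly (post =
    # pre + delta), which slightly inflates the post-lpt marginal SD but
    # keeps the planted rank correlation exact.
    r = 2.0 * np.sin(np.pi * spec.rho_star / 6.0)
    e = rng.standard_normal(n)
    z_lpt = r * z_ba4 + np.sqrt(1.0 - r * r) * e
    sd_dlpt = np.sqrt(
        spec.lpt.pre_sd**2
        + spec.lpt.post_sd**2
        - 2.0 * rho * spec.lpt.pre_sd * spec.lpt.post_sd
    )
    lpt_pre = spec.lpt.pre_mean + spec.lpt.pre_sd * rng.standard_normal(n)
    d_lpt = (spec.lpt.post_mean - spec.lpt.pre_mean) + sd_dlpt * z_lpt
    lpt_pre = np.minimum(lpt_pre, _LN_CAP)
    lpt_post = np.minimum(lpt_pre + d_lpt, _LN_CAP)

    fma_pre, fma_post, _ = _paired_normal(rng, n, spec.fma, rho)
    fma_pre = np.clip(np.rint(fma_pre), 0, 66).astype(int)
    fma_post = np.clip(np.rint(fma_post), 0, 66).astype(int)

    score_rows = []
    for tp, fma, lpt in (("pre", fma_pre, lpt_pre), ("post", fma_post, lpt_post)):
        row = {"subject": subjects, "timepoint": tp, "fma_total": fma}
        times = np.exp(lpt)
        for k in range(1, N_WMFT_TASKS + 1):
            row[f"task_{k:02d}"] = times
        score_rows.append(pd.DataFrame(row))
    scores = pd.concat(score_rows, ignore_index=True)
    return CohortTable(scores=scores, rois=rois)
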