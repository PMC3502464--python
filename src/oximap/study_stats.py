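"""Cohort summaries and paired pre/post statistics for oximetry studies.

Mirrors the analysis of a paired occlusion experiment: per-arm mean +/- SD
summaries grouped by (timepoint, vessel kind, region), paired two-tailed
Student t-tests of pre- versus post-occlusion saturation, and per-animal
arteriovenous (AV) differences. Saturations are reported on the percent scale
(0-100); no multiple-testing correction is applied, matching per-comparison
reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatsResult",
    "paired_ttest",
    "summarize_arms",
    "av_difference",
    "simulate_paired_cohort",
    "run_paired_study",
    "measurements_from_results",
]

log = logging.getLogger(__name__)

GROUP_KEYS = ["timepoint", "kind", "region"]


@dataclass
class StatsResult:
    """Outcome of one paired comparison."""

    label: str
    n: int
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    mean_diff: float   # pre - post
    t: float
    df: int
    p: float


def paired_ttest(pre, post, label: str = "") -> StatsResult:
    """Paired two-tailed Student t-test on pre vs post measurements.

    t = mean(d) / (sd(d)/sqrt(n)) with d = pre - post and the sample SD
    (n-1 denominator); two-tailed p from Student's t with df = n - 1.
    Degenerate inputs: identical pairs give t = 0, p = 1; zero-variance
    differences with nonzero mean give a p = 0 sentinel with a warning.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    n = len(pre)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = pre - post
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            warnings.warn("zero-variance differences with nonzero mean; p set to 0")
            t, p = np.inf if mean_d > 0 else -np.inf, 0.0
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return StatsResult(
        label=label,
        n=n,
        mean_pre=float(pre.mean()),
        sd_pre=float(pre.std(ddof=1)),
        mean_post=float(post.mean()),
        sd_post=float(post.std(ddof=1)),
        mean_diff=mean_d,
        t=float(t),
        df=df,
        p=p,
    )


def summarize_arms(data: pd.DataFrame) -> pd.DataFrame:
    """Per-arm n, mean and SD of saturation percent.

    ``data`` holds rows (animal, timepoint, kind, region, so2_percent);
    grouping is by (timepoint, kind, region). Single-measurement arms report
    SD 0 with ``single_flag`` set.
    """
    if data.empty:
        return pd.DataFrame(
            columns=GROUP_KEYS + ["n", "mean_so2", "sd_so2", "single_flag"]
        )
    g = data.groupby(GROUP_KEYS)["so2_percent"]
    out = g.agg(n="size", mean_so2="mean", sd_so2=lambda x: x.std(ddof=1)).reset_index()
    out["single_flag"] = out["n"] == 1
    out["sd_so2"] = out["sd_so2"].fillna(0.0)
    return out


def av_difference(data: pd.DataFrame) -> pd.DataFrame:
    """Arteriovenous saturation difference per (animal, timepoint, region).

    AV = artery% - vein%, a proxy for tissue oxygen extraction. Units missing
    either vessel are skipped with a logged warning.
    """
    rows = []
    for (animal, tp, region), grp in data.groupby(["animal", "timepoint", "region"]):
        kinds = grp.set_index("kind")["so2_percent"]
        if "artery" not in kinds.index or "vein" not in kinds.index:
            log.warning(
                "AV difference: missing partner vessel for animal=%s %s/%s; skipped",
                animal, tp, region,
            )
            continue
        rows.append(
            {
                "animal": animal,
                "timepoint": tp,
                "region": region,
                "av_difference": float(kinds["artery"]) - float(kinds["vein"]),
            }
        )
    return pd.DataFrame(rows, columns=["animal", "timepoint", "region", "av_difference"])


def run_paired_study(
    data: pd.DataFrame, pre: str = "baseline", post: str = "1h"
) -> pd.DataFrame:
    """Paired pre-vs-post t-tests for every (kind, region) arm.

    Measurements are averaged per animal within each arm and timepoint before
    testing, so animals (not vessel segments) are the unit of analysis.
    """
    results = []
    for (kind, region), grp in data.groupby(["kind", "region"]):
        per_animal = (
            grp.groupby(["animal", "timepoint"])["so2_percent"].mean().unstack()
        )
        if pre not in per_animal or post not in per_animal:
            continue
        paired = per_animal[[pre, post]].dropna()
        if len(paired) < 2:
            continue
        res = paired_ttest(paired[pre], paired[post], label=f"{region} {kind}")
        results.append(
            {
                "kind": kind,
                "region": region,
                "n": res.n,
                "mean_pre": res.mean_pre,
                "sd_pre": res.sd_pre,
                "mean_post": res.mean_post,
                "sd_post": res.sd_post,
                "mean_diff": res.mean_diff,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(results)


def simulate_paired_cohort(
    n: int,
    mean_pre: float,
    mean_post: float,
    sd_pre: float,
    sd_post: float,
    rho: float = 0.7,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one paired cohort from a correlated bivariate normal.

    ``rho`` is the within-animal pre/post correlation implied by the paired
    design. Used for type-I-error and power calibration of the paired t-test.
    """
    rng = rng or np.random.default_rng()
    cov = np.array(
        [
            [sd_pre**2, rho * sd_pre * sd_post],
            [rho * sd_pre * sd_post, sd_post**2],
        ]
    )
    draws = rng.multivariate_normal([mean_pre, mean_post], cov, size=n)
    return draws[:, 0], draws[:, 1]


def measurements_from_results(results: pd.DataFrame) -> pd.DataFrame:
    """Validate/normalize a measurements table to the cohort schema."""
    required = {"animal", "timepoint", "kind", "region", "so2_percent"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"measurements table missing columns: {sorted(missing)}")
    out = results.copy()
    bad = out[(out["so2_percent"] < 0) | (out["so2_percent"] > 100)]
    if not bad.empty:
        raise ValueError("so2_percent outside [0, 100]")
    return out
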