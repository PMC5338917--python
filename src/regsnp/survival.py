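"""Expression z-score stratification and biochemical-recurrence survival.

For each candidate gene, tumor expression is converted to a z-score against
the normal-sample distribution, z = (x - mu) / sigma with mu and sigma the
mean and (n-1) standard deviation of the normal samples.  Tumors are split
into positive- and negative-z groups; the 75% most extreme of each side
(floor rule, minimum one sample) form the high- and low-expression strata,
tumors with z nearest zero are excluded as uninformative.  The strata are
compared with Kaplan-Meier curves and a two-sided log-rank test on
time-to-biochemical-recurrence.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .eqtl import ExpressionMatrix

__all__ = [
    "SurvivalRecord",
    "StratificationResult",
    "zscore_vs_normals",
    "stratify_by_zscore",
    "km_curve",
    "logrank_test",
    "risk_scan",
    "read_clinical",
    "risk_results_frame",
]

KEEP_FRACTION = 0.75


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # months of follow-up or time to recurrence
    event: bool  # biochemical recurrence observed

    def __post_init__(self) -> None:
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise ValueError(
                f"sample {self.sample_id}: time must be finite and >= 0"
            )


@dataclass
class StratificationResult:
    gene_id: str
    assignments: dict[str, str] = field(default_factory=dict)  # high/low/excluded
    n_high: int = 0
    n_low: int = 0
    logrank_stat: float | None = None
    p_value: float | None = None

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def zscore_vs_normals(
    tumor_values: Sequence[float] | np.ndarray,
    normal_values: Sequence[float] | np.ndarray,
) -> np.ndarray | None:
    """Per-tumor z-scores against the normal mean and sample (n-1) SD.

    Returns None (with a warning) when the normal SD is zero — the gene is
    unusable for stratification.  Requires at least two normal samples.
    """
    normal = np.asarray(normal_values, dtype=float)
    tumor = np.asarray(tumor_values, dtype=float)
    if len(normal) < 2:
        raise ValueError("need >= 2 normal samples to define the z-score")
    mu = normal.mean()
    sigma = normal.std(ddof=1)
    if sigma == 0:
        warnings.warn(
            "normal-sample SD is zero; gene excluded from stratification",
            stacklevel=2,
        )
        return None
    return (tumor - mu) / sigma


def stratify_by_zscore(
    z_scores: pd.Series, keep_fraction: float = KEEP_FRACTION
) -> dict[str, str]:
    """Label tumors high/low/excluded by the extreme-75% rule.

    Among positive-z tumors the floor(keep_fraction * n_pos) highest (at
    least 1) are 'high'; among negative-z tumors the floor(keep_fraction *
    n_neg) lowest (at least 1) are 'low'; the remainder — z nearest zero —
    are 'excluded'.  Ties are broken by stable sample_id order, so the
    assignment is invariant to input permutation.  Requires at least one
    tumor of each sign (z exactly 0 counts as neither).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    z = z_scores.astype(float)
    pos = z[z > 0]
    neg = z[z < 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(
            "need at least one positive and one negative z-score to stratify"
        )
    n_high = max(1, math.floor(keep_fraction * len(pos)))
    n_low = max(1, math.floor(keep_fraction * len(neg)))
    pos_order = sorted(pos.index, key=lambda s: (-pos[s], s))
    neg_order = sorted(neg.index, key=lambda s: (neg[s], s))
    labels = {s: "excluded" for s in z.index}
    for s in pos_order[:n_high]:
        labels[s] = "high"
    for s in neg_order[:n_low]:
        labels[s] = "low"
    return labels


def km_curve(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a frame with columns ``time`` and ``survival``, stepping at each
    distinct event time.  A dataset with only censored observations yields
    the constant-1 curve.
    """
    if not records:
        raise ValueError("no survival records")
    times = [r.time for r in records]
    events = [bool(r.event) for r in records]
    km = KaplanMeierFitter().fit(times, events)
    sf = km.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(
    group_high: Sequence[SurvivalRecord], group_low: Sequence[SurvivalRecord]
) -> tuple[float, float] | None:
    """Two-sided two-group log-rank test (chi-square, 1 df).

    Returns (statistic, p_value), or None when no events occurred in either
    group (untestable).
    """
    if not group_high or not group_low:
        raise ValueError("both groups must be nonempty")
    if not any(r.event for r in group_high) and not any(r.event for r in group_low):
        return None
    res = _ll_logrank(
        [r.time for r in group_high],
        [r.time for r in group_low],
        event_observed_A=[bool(r.event) for r in group_high],
        event_observed_B=[bool(r.event) for r in group_low],
    )
    return float(res.test_statistic), float(res.p_value)


def risk_scan(
    expr: ExpressionMatrix,
    clinical: Sequence[SurvivalRecord],
    gene_ids: Sequence[str],
    keep_fraction: float = KEEP_FRACTION,
) -> list[StratificationResult]:
    """Per-gene stratification and log-rank test on recurrence-free survival.

    Only tumors present in both the expression matrix and the clinical table
    enter the analysis; genes with zero normal SD or single-signed z-scores
    are returned untestable.
    """
    by_sample = {r.sample_id: r for r in clinical}
    tumor = [s for s in expr.samples_of_class("tumor") if s in by_sample]
    normal = expr.samples_of_class("normal")
    results: list[StratificationResult] = []
    for gid in gene_ids:
        res = StratificationResult(gid)
        results.append(res)
        if gid not in expr.values.index or len(tumor) == 0:
            continue
        z = zscore_vs_normals(
            expr.values.loc[gid, tumor].to_numpy(dtype=float),
            expr.values.loc[gid, normal].to_numpy(dtype=float),
        )
        if z is None:
            continue
        zs = pd.Series(z, index=tumor)
        try:
            res.assignments = stratify_by_zscore(zs, keep_fraction)
        except ValueError:
            continue
        high = [by_sample[s] for s, lab in res.assignments.items() if lab == "high"]
        low = [by_sample[s] for s, lab in res.assignments.items() if lab == "low"]
        res.n_high, res.n_low = len(high), len(low)
        lr = logrank_test(high, low)
        if lr is not None:
            res.logrank_stat, res.p_value = lr
    return results


def read_clinical(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: clinical table missing columns {sorted(missing)}")
    return [
        SurvivalRecord(str(r.sample_id), float(r.time_months), bool(int(r.event)))
        for r in df.itertuples()
    ]


def risk_results_frame(results: Sequence[StratificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "logrank_stat": r.logrank_stat,
                "logrank_p": r.p_value,
            }
            for r in results
        ],
        columns=["gene_id", "n_high", "n_low", "logrank_stat", "logrank_p"],
    )
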