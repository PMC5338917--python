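"""Tumor-versus-normal differential expression call for candidate genes.

A gene is called differentially expressed when its tumor/normal fold change
exceeds 1.5x in either direction AND the two-sample test p-value is below
0.01.  Fold change is computed on the linear normalized scale with a +1
offset guarding zero means; the p-value comes from Welch's t-test on
log2(x+1) values (a Wilcoxon rank-sum option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eqtl import ExpressionMatrix

__all__ = ["DEResult", "de_call", "de_results_frame"]

#: offset on linear normalized values before the ratio
FC_OFFSET = 1.0


@dataclass
class DEResult:
    gene_id: str
    mean_tumor: float | None = None
    mean_normal: float | None = None
    fold_change: float | None = None  # tumor/normal, linear scale, >1 = tumor-high
    log2_fc: float | None = None
    p_value: float | None = None
    is_de: bool = False

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def de_call(
    expr: ExpressionMatrix,
    gene_ids: Sequence[str],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.01,
    test: str = "welch",
) -> list[DEResult]:
    """Per-gene fold change and tumor-vs-normal test.

    ``is_de`` is true iff |log2 fold change| > log2(fc_threshold) and
    p < p_threshold.  A class with fewer than 2 samples leaves the gene
    untestable (flagged, never a crash).
    """
    if test not in ("welch", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")
    tumor = expr.samples_of_class("tumor")
    normal = expr.samples_of_class("normal")
    results: list[DEResult] = []
    log_fc_min = np.log2(fc_threshold)
    for gid in gene_ids:
        res = DEResult(gid)
        if gid not in expr.values.index:
            results.append(res)
            continue
        tv = expr.values.loc[gid, tumor].to_numpy(dtype=float)
        nv = expr.values.loc[gid, normal].to_numpy(dtype=float)
        if len(tv) >= 1 and len(nv) >= 1:
            res.mean_tumor = float(tv.mean())
            res.mean_normal = float(nv.mean())
            res.fold_change = (res.mean_tumor + FC_OFFSET) / (
                res.mean_normal + FC_OFFSET
            )
            res.log2_fc = float(np.log2(res.fold_change))
        if len(tv) >= 2 and len(nv) >= 2:
            if test == "welch":
                _, p = stats.ttest_ind(
                    np.log2(tv + 1.0), np.log2(nv + 1.0), equal_var=False
                )
            else:
                _, p = stats.mannwhitneyu(tv, nv, alternative="two-sided")
            res.p_value = float(p)
            res.is_de = bool(
                abs(res.log2_fc) > log_fc_min and res.p_value < p_threshold
            )
        results.append(res)
    return results


def de_results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mean_tumor": r.mean_tumor,
                "mean_normal": r.mean_normal,
                "fold_change": r.fold_change,
                "log2_fc": r.log2_fc,
                "p_value": r.p_value,
                "is_de": r.is_de,
            }
            for r in results
        ],
        columns=[
            "gene_id",
            "mean_tumor",
            "mean_normal",
            "fold_change",
            "log2_fc",
            "p_value",
            "is_de",
        ],
    )
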