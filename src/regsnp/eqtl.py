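"""cis-eQTL scan: genotype-vs-expression association by one-way ANOVA.

For every SNP that survived the regulatory-region filter, genes whose
transcription start site lies within a +/-25 kb window of the SNP are
tested: samples are grouped by the genotype class they carry (0, 1 or 2
copies of allele B), and expression differences across groups are assessed
with a one-way ANOVA F test.  Significance across all tested SNP-gene pairs
is controlled with Benjamini-Hochberg FDR.

The ANOVA is computed from explicit sums of squares so that degenerate
inputs (too-small groups, zero within-group variance) have a defined,
documented outcome instead of a library-dependent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import SNPVariant

__all__ = [
    "GeneAnnotation",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "EQTLResult",
    "drop_silent_genes",
    "genes_near_snp",
    "anova_eqtl",
    "run_eqtl_scan",
    "read_genotype_matrix",
    "read_expression_matrix",
    "read_gene_annotation",
    "eqtl_results_frame",
]

#: genotype classes with fewer samples than this are dropped from the test
MIN_GROUP_SIZE = 3

#: default cis window on either side of the SNP (bp)
DEFAULT_WINDOW = 25_000


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int  # 1-based transcription start position
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"gene {self.gene_id}: TSS must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-B copy counts; NaN marks a missing call."""

    calls: pd.DataFrame  # index: sample_ids, columns: snp_ids, values 0/1/2/NaN

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"genotype call at sample {self.calls.index[bad[0]]!r}, "
                f"snp {self.calls.columns[bad[1]]!r} not in {{0,1,2,NA}}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.calls.columns)


@dataclass
class ExpressionMatrix:
    """Genes x samples normalized expression with tumor/normal labels."""

    values: pd.DataFrame  # index: gene_ids, columns: sample_ids
    sample_class: pd.Series  # per-sample label in {tumor, normal}

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        missing = set(self.values.columns) - set(self.sample_class.index)
        if missing:
            raise ValueError(f"samples without class label: {sorted(missing)[:5]}")
        bad = set(self.sample_class.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of_class(self, cls: str) -> list[str]:
        keep = self.sample_class[self.sample_class == cls].index
        return [s for s in self.values.columns if s in set(keep)]


@dataclass
class EQTLResult:
    snp_id: str
    gene_id: str
    group_sizes: dict[int, int] = field(default_factory=dict)
    group_means: dict[int, float] = field(default_factory=dict)
    f_stat: float | None = None
    p_value: float | None = None
    significant: bool = False

    @property
    def testable(self) -> bool:
        return self.p_value is not None


def drop_silent_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes whose values are zero in every sample; order preserved."""
    keep = ~(expr.values == 0).all(axis=1)
    return ExpressionMatrix(expr.values.loc[keep], expr.sample_class)


def genes_near_snp(
    snp: SNPVariant,
    genes: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
) -> list[GeneAnnotation]:
    """Genes on the SNP's chromosome with |TSS - pos| <= window (inclusive),
    ordered by distance ascending with ties broken by gene_id."""
    if window <= 0:
        raise ValueError("window must be > 0")
    near = [
        g for g in genes if g.chrom == snp.chrom and abs(g.tss - snp.pos) <= window
    ]
    near.sort(key=lambda g: (abs(g.tss - snp.pos), g.gene_id))
    return near


def anova_eqtl(
    genotypes: Sequence[float] | np.ndarray,
    expression: Sequence[float] | np.ndarray,
    snp_id: str = "",
    gene_id: str = "",
    min_group_size: int = MIN_GROUP_SIZE,
) -> EQTLResult:
    """One-way ANOVA of expression across observed genotype classes.

    Samples with a missing genotype are excluded pairwise.  Genotype classes
    with fewer than ``min_group_size`` samples are dropped; if fewer than two
    classes remain the pair is untestable (``p_value is None``).  Zero
    within-group variance with unequal group means yields the p = 0 bound
    explicitly.
    """
    g = np.asarray(genotypes, dtype=float)
    x = np.asarray(expression, dtype=float)
    if g.shape != x.shape:
        raise ValueError("genotype and expression vectors differ in length")
    keep = ~np.isnan(g) & ~np.isnan(x)
    g, x = g[keep], x[keep]

    groups: list[np.ndarray] = []
    sizes: dict[int, int] = {}
    means: dict[int, float] = {}
    for cls in (0, 1, 2):
        vals = x[g == cls]
        if len(vals) == 0:
            continue
        sizes[cls] = len(vals)
        means[cls] = float(vals.mean())
        if len(vals) >= min_group_size:
            groups.append(vals)

    res = EQTLResult(snp_id, gene_id, group_sizes=sizes, group_means=means)
    if len(groups) < 2:
        return res

    n = sum(len(v) for v in groups)
    k = len(groups)
    grand = sum(v.sum() for v in groups) / n
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups)
    dfb, dfw = k - 1, n - k
    if dfw <= 0:
        return res
    if ssw == 0.0:
        if ssb == 0.0:
            res.f_stat, res.p_value = 0.0, 1.0
        else:
            res.f_stat, res.p_value = float("inf"), 0.0
        return res
    f = (ssb / dfb) / (ssw / dfw)
    res.f_stat = float(f)
    res.p_value = float(stats.f.sf(f, dfb, dfw))
    return res


def run_eqtl_scan(
    snps: Sequence[SNPVariant],
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    genes: Sequence[GeneAnnotation],
    window: int = DEFAULT_WINDOW,
    fdr: float = 0.05,
    min_group_size: int = MIN_GROUP_SIZE,
    log2_transform: bool = False,
) -> list[EQTLResult]:
    """Test every SNP-gene pair within the cis window on tumor samples.

    Expression and genotype matrices are intersected by sample id (tumor
    samples only); ``significant`` is set by Benjamini-Hochberg FDR across
    all testable pairs at level ``fdr``.
    """
    tumor = expr.samples_of_class("tumor")
    shared = [s for s in tumor if s in set(genotypes.sample_ids)]
    if not shared:
        raise ValueError(
            "no overlapping tumor samples between expression and genotype matrices"
        )
    gene_index = {g.gene_id for g in genes} & set(expr.gene_ids)
    values = expr.values[shared]
    calls = genotypes.calls.loc[shared]
    if log2_transform:
        values = np.log2(values + 1.0)

    results: list[EQTLResult] = []
    for snp in snps:
        if snp.snp_id not in calls.columns:
            continue
        gvec = calls[snp.snp_id].to_numpy(dtype=float)
        for gene in genes_near_snp(snp, genes, window):
            if gene.gene_id not in gene_index:
                continue
            xvec = values.loc[gene.gene_id].to_numpy(dtype=float)
            results.append(
                anova_eqtl(
                    gvec, xvec, snp.snp_id, gene.gene_id, min_group_size
                )
            )
    testable = [r for r in results if r.testable]
    if testable:
        pvals = np.array([r.p_value for r in testable])
        reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for r, rej in zip(testable, reject):
            r.significant = bool(rej)
    return results


# ---------------------------------------------------------------------------
# I/O

def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix(df)


def read_expression_matrix(
    expr_path: str | Path, classes_path: str | Path
) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    cls = pd.read_csv(classes_path, sep="\t", index_col=0)["class"]
    return ExpressionMatrix(values, cls)


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneAnnotation(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
        for r in df.itertuples()
    ]


def eqtl_results_frame(results: Sequence[EQTLResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "snp_id": r.snp_id,
                "gene_id": r.gene_id,
                "n_groups": len(r.group_sizes),
                "group_sizes": ";".join(
                    f"{k}:{v}" for k, v in sorted(r.group_sizes.items())
                ),
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "gene_id",
            "n_groups",
            "group_sizes",
            "f_stat",
            "p_value",
            "significant",
        ],
    )
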