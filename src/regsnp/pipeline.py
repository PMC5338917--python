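"""End-to-end orchestration: regions -> SNP filter -> eQTL -> motif -> DE -> risk.

A candidate regulatory SNP is one that (1) falls inside a tissue-specific
regulatory region, (2) has a significant cis-eQTL association with a nearby
gene, and (3) changes a TF binding motif (disrupt or create call).
Differential expression and recurrence-risk results annotate the candidate
table; they are not filters.  Attrition counts are recorded at every stage.

Every run is deterministic given fixed inputs and configuration; re-running
into the same output directory reproduces byte-identical artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from .intervals import (
    RegionSet,
    SNPVariant,
    RegionHit,
    merge_intervals,
    union_tf_peaks,
    intersect_regions,
    snps_in_regions,
    annotate_tf_support,
    check_chrom_naming,
    read_bed,
    write_bed,
    read_snp_manifest,
)
from .eqtl import (
    run_eqtl_scan,
    drop_silent_genes,
    read_genotype_matrix,
    read_expression_matrix,
    read_gene_annotation,
    eqtl_results_frame,
    EQTLResult,
)
from .motifs import (
    SNPContext,
    parse_motif_file,
    scan_snps_for_motif_change,
    motif_change_snp_ids,
    AlleleEffectResult,
)
from .diffexpr import de_call, de_results_frame
from .survival import risk_scan, read_clinical, risk_results_frame

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "attrition_summary",
    "context_from_fasta",
    "build_regulatory_regions",
]


@dataclass
class PipelineConfig:
    """Input paths and per-stage thresholds for one pipeline run."""

    dhs_bed: str
    mark_beds: list[str]
    tf_beds: dict[str, str]
    snp_manifest: str
    genotypes: str
    expression: str
    classes: str
    genes: str
    clinical: str
    fasta: str
    motifs: str
    out_dir: str
    window: int = 25_000
    fdr: float = 0.05
    fc_threshold: float = 1.5
    de_p: float = 0.01
    flank: int = 20
    delta_min: float = 2.0
    keep_fraction: float = 0.75
    promoter_margin: int = 2_000
    min_group_size: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class PipelineResult:
    report: pd.DataFrame
    attrition: pd.DataFrame
    regulatory_regions: RegionSet
    region_hits: list[RegionHit]
    eqtl_results: list[EQTLResult]
    motif_results: list[AlleleEffectResult]
    de_frame: pd.DataFrame = field(default_factory=pd.DataFrame)
    risk_frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def context_from_fasta(
    fasta: Fasta, snp: SNPVariant, flank: int = 20, strict: bool = False
) -> SNPContext:
    """Cut the ±flank bp sequence around a 1-based SNP position.

    Windows running off a chromosome end are padded with N.  When the
    reference base matches neither allele the center is replaced by allele A
    (with a warning) unless ``strict``.
    """
    chrom_len = len(fasta[snp.chrom])
    lo = snp.pos - 1 - flank
    hi = snp.pos + flank  # exclusive, 0-based
    seq = str(fasta[snp.chrom][max(0, lo) : min(chrom_len, hi)]).upper()
    seq = "N" * max(0, -lo) + seq + "N" * max(0, hi - chrom_len)
    center = seq[flank]
    if center not in (snp.allele_a, snp.allele_b):
        msg = (
            f"SNP {snp.snp_id}: reference base {center!r} matches neither "
            f"allele ({snp.allele_a}/{snp.allele_b})"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + "; substituting allele A", stacklevel=2)
        seq = seq[:flank] + snp.allele_a + seq[flank + 1 :]
    return SNPContext(snp, seq)


def build_regulatory_regions(
    dhs: RegionSet, marks: list[RegionSet], tf_sets: dict[str, RegionSet]
) -> tuple[RegionSet, list[list[str]]]:
    """Regulatory regions = union(TF peaks) ∩ union(DHS, marks).

    Returns the merged region set and, per region, the contributing TF names.
    """
    check_chrom_naming(dhs, *marks, *tf_sets.values())
    active_ivs = list(dhs.intervals)
    for m in marks:
        active_ivs += m.intervals
    active = merge_intervals(RegionSet(active_ivs))
    tf_union = union_tf_peaks(list(tf_sets.values()))
    regulatory = intersect_regions(tf_union, active)
    support = annotate_tf_support(regulatory, tf_sets)
    regulatory.support_count = [max(1, len(s)) for s in support]
    return regulatory, support


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order, writing per-stage artifacts to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    attrition_rows: list[dict] = []

    def log_stage(stage: str, n_in: int, n_out: int) -> None:
        attrition_rows.append({"stage": stage, "items_in": n_in, "items_out": n_out})

    # stage 1: regulatory regions
    dhs = read_bed(config.dhs_bed, "DHS")
    marks = [read_bed(p, "mark") for p in config.mark_beds]
    tf_sets = {tf: read_bed(p, tf) for tf, p in config.tf_beds.items()}
    n_peaks = len(dhs) + sum(len(m) for m in marks) + sum(
        len(s) for s in tf_sets.values()
    )
    regulatory, region_tfs = build_regulatory_regions(dhs, marks, tf_sets)
    write_bed(regulatory, out / "regulatory_regions.bed")
    log_stage("regulatory_regions", n_peaks, len(regulatory))

    # stage 2: SNPs in regions
    snps = read_snp_manifest(config.snp_manifest)
    hits = snps_in_regions(snps, regulatory)
    log_stage("snps_in_regions", len(snps), len(hits))
    region_index = {id(iv): i for i, iv in enumerate(regulatory.intervals)}
    hit_frame = pd.DataFrame(
        {
            "snp_id": [h.snp.snp_id for h in hits],
            "chrom": [h.snp.chrom for h in hits],
            "pos": [h.snp.pos for h in hits],
            "region_start": [h.region.start for h in hits],
            "region_end": [h.region.end for h in hits],
            "tfs": [
                ";".join(region_tfs[region_index[id(h.region)]]) for h in hits
            ],
        }
    )
    hit_frame.to_csv(out / "snps_in_regions.tsv", sep="\t", index=False)

    # stage 3: cis-eQTL scan on region SNPs (tumor samples)
    genotypes = read_genotype_matrix(config.genotypes)
    expr = drop_silent_genes(
        read_expression_matrix(config.expression, config.classes)
    )
    genes = read_gene_annotation(config.genes)
    hit_snps = [h.snp for h in hits]
    eqtl_results = run_eqtl_scan(
        hit_snps,
        genotypes,
        expr,
        genes,
        window=config.window,
        fdr=config.fdr,
        min_group_size=config.min_group_size,
    )
    eqtl_results_frame(eqtl_results).to_csv(
        out / "eqtl_results.tsv", sep="\t", index=False
    )
    sig_pairs = [r for r in eqtl_results if r.significant]
    sig_snp_ids = {r.snp_id for r in sig_pairs}
    log_stage("eqtl_pairs", len(eqtl_results), len(sig_pairs))

    # stage 4: motif change scan on eQTL-significant SNPs
    pwms = parse_motif_file(config.motifs)
    fasta = Fasta(config.fasta)
    order = [s for s in hit_snps if s.snp_id in sig_snp_ids]
    contexts = [
        context_from_fasta(fasta, s, flank=config.flank) for s in order
    ]
    motif_results = scan_snps_for_motif_change(
        contexts, pwms, delta_min=config.delta_min
    )
    motif_frame = pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "tf": r.tf_name,
                "score_a": round(r.best_score_a, 6),
                "score_b": round(r.best_score_b, 6),
                "delta": round(r.delta, 6),
                "offset_a": r.best_offset_a,
                "strand_a": r.best_strand_a,
                "call": r.call,
            }
            for r in motif_results
        ],
        columns=[
            "snp_id",
            "tf",
            "score_a",
            "score_b",
            "delta",
            "offset_a",
            "strand_a",
            "call",
        ],
    )
    motif_frame.to_csv(out / "motif_effects.tsv", sep="\t", index=False)
    changed = set(motif_change_snp_ids(motif_results))
    log_stage("motif_change_snps", len(order), len(changed))

    # candidates: region ∧ eQTL-significant ∧ motif-changing
    candidate_pairs = [r for r in sig_pairs if r.snp_id in changed]
    candidate_genes: list[str] = []
    for r in candidate_pairs:
        if r.gene_id not in candidate_genes:
            candidate_genes.append(r.gene_id)

    # stage 5: DE annotation of candidate genes
    de_results = de_call(
        expr,
        candidate_genes,
        fc_threshold=config.fc_threshold,
        p_threshold=config.de_p,
    )
    de_frame = de_results_frame(de_results)
    de_frame.to_csv(out / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    n_de = int(de_frame["is_de"].sum()) if len(de_frame) else 0
    log_stage("de_genes", len(candidate_genes), n_de)

    # stage 6: recurrence-risk annotation of candidate genes
    clinical = read_clinical(config.clinical)
    risk_results = risk_scan(
        expr, clinical, candidate_genes, keep_fraction=config.keep_fraction
    )
    risk_frame = risk_results_frame(risk_results)
    risk_frame.to_csv(
        out / "risk_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    n_risk = int(
        ((risk_frame["logrank_p"] < 0.05) & risk_frame["logrank_p"].notna()).sum()
    ) if len(risk_frame) else 0
    log_stage("risk_genes", len(candidate_genes), n_risk)

    # candidate report
    hit_by_id = {h.snp.snp_id: h for h in hits}
    tf_by_id = {
        h.snp.snp_id: ";".join(region_tfs[region_index[id(h.region)]]) for h in hits
    }
    de_by_gene = {r.gene_id: r for r in de_results}
    risk_by_gene = {r.gene_id: r for r in risk_results}
    motif_by_snp: dict[str, list[AlleleEffectResult]] = {}
    for r in motif_results:
        motif_by_snp.setdefault(r.snp_id, []).append(r)
    gene_by_id = {g.gene_id: g for g in genes}

    rows = []
    for r in candidate_pairs:
        hit = hit_by_id[r.snp_id]
        calls = [
            m for m in motif_by_snp.get(r.snp_id, []) if m.call in ("disrupt", "create")
        ]
        de_r = de_by_gene.get(r.gene_id)
        risk_r = risk_by_gene.get(r.gene_id)
        gene = gene_by_id.get(r.gene_id)
        promoter = (
            gene is not None
            and abs(hit.snp.pos - gene.tss) <= config.promoter_margin
        )
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": hit.snp.chrom,
                "pos": hit.snp.pos,
                "region_start": hit.region.start,
                "region_end": hit.region.end,
                "region_tfs": tf_by_id[r.snp_id],
                "gene_id": r.gene_id,
                "eqtl_p": r.p_value,
                "eqtl_significant": r.significant,
                "motif_calls": ";".join(
                    f"{m.tf_name}:{m.call}:{m.delta:.3f}" for m in calls
                ),
                "location": "promoter" if promoter else "distal",
                "de_is_de": bool(de_r.is_de) if de_r else False,
                "de_p": de_r.p_value if de_r else None,
                "risk_p": risk_r.p_value if risk_r else None,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "chrom",
            "pos",
            "region_start",
            "region_end",
            "region_tfs",
            "gene_id",
            "eqtl_p",
            "eqtl_significant",
            "motif_calls",
            "location",
            "de_is_de",
            "de_p",
            "risk_p",
        ],
    )
    report.to_csv(
        out / "candidate_report.tsv", sep="\t", index=False, float_format="%.6g"
    )

    attrition = pd.DataFrame(
        attrition_rows, columns=["stage", "items_in", "items_out"]
    )
    attrition.to_csv(out / "attrition.tsv", sep="\t", index=False)
    return PipelineResult(
        report=report,
        attrition=attrition,
        regulatory_regions=regulatory,
        region_hits=hits,
        eqtl_results=eqtl_results,
        motif_results=motif_results,
        de_frame=de_frame,
        risk_frame=risk_frame,
    )


def attrition_summary(result: PipelineResult) -> pd.DataFrame:
    """Per-stage item counts (stage, items_in, items_out)."""
    return result.attrition.copy()
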