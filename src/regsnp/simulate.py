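"""Seeded synthetic-data generator for the whole pipeline.

Emulates the processed inputs the analysis consumes — peak BED files for
open chromatin, an active-enhancer histone mark and five prostate TFs;
an array SNP manifest with reference FASTA; Hardy-Weinberg genotype calls;
RSEM-like positive normalized expression; and time-to-biochemical-recurrence
clinical records — with a configurable number of *planted* regulatory SNPs
that simultaneously (a) sit inside a DHS ∩ H3K27ac ∩ TF-peak region,
(b) carry a high-information TF motif consensus under one allele and a
broken core base under the other, (c) drive cis expression of a target gene
whose TSS lies within the 25 kb window, and (d) mark a gene whose high
expression tail carries elevated recurrence hazard.

All randomness flows from a single seed through named child streams (one
per artifact) so adding an artifact never perturbs existing ones; two runs
with the same config are byte-identical across all emitted files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    RegionSet,
    SNPVariant,
    merge_intervals,
    union_tf_peaks,
    intersect_regions,
    snps_in_regions,
    write_bed,
    write_snp_manifest,
)
from .eqtl import ExpressionMatrix, GenotypeMatrix, GeneAnnotation
from .motifs import BASES, PWMModel, SNPContext, allele_effect, write_motif_file
from .survival import SurvivalRecord

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_regions_and_snps",
    "simulate_survival",
    "simulate_all",
    "make_planted_pwm",
]

TF_NAMES = ("AR", "FOXA1", "GATA2", "NKX3-1", "HOXB13")

# named child-stream order: appending keeps earlier artifacts reproducible
_STREAMS = (
    "motifs",
    "genome",
    "peaks",
    "snps",
    "genes",
    "genotypes",
    "expression",
    "survival",
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Sample counts emulate a TCGA-like cohort at desk scale; the planted
    effect sizes are the conditions under which recovery is evaluated.
    """

    seed: int = 0
    n_tumor: int = 200
    n_normal: int = 50
    n_snps: int = 500
    n_genes: int = 300
    n_planted: int = 5
    n_in_region_decoys: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    planted_maf_range: tuple[float, float] = (0.25, 0.45)
    eqtl_beta: float = 1.0  # additive effect per allele copy, in noise-SD units
    noise_sd: float = 0.5  # expression noise on the log scale
    de_fold: float = 3.0  # tumor/normal fold change planted on DE genes
    hazard_ratio: float = 3.0
    censor_rate: float = 0.3
    base_hazard: float = 1.0 / 60.0  # events per month
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    motif_length: int = 8
    motif_info_bits: float = 14.0
    flank: int = 20
    n_dhs_peaks: int = 150  # per chromosome
    n_mark_peaks: int = 150
    n_tf_peaks: int = 100  # per TF per chromosome

    def __post_init__(self) -> None:
        for name in ("n_tumor", "n_normal", "n_snps", "n_genes", "n_planted"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.n_planted + self.n_in_region_decoys > self.n_snps:
            raise ValueError("planted + in-region decoys exceed n_snps")

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


@dataclass
class PlantedEffect:
    snp_id: str
    tf: str
    target_gene: str
    eqtl_beta: float
    motif_core_offset: int  # motif start relative to the SNP base
    de_direction: int  # +1 tumor-high, -1 tumor-low, 0 none
    is_risk_gene: bool


@dataclass
class GroundTruth:
    planted: list[PlantedEffect] = field(default_factory=list)
    in_region_decoys: list[str] = field(default_factory=list)
    outside_decoys: list[str] = field(default_factory=list)
    risk_gene: str | None = None

    @property
    def planted_snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.planted]

    @property
    def planted_gene_ids(self) -> list[str]:
        return [p.target_gene for p in self.planted]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "in_region_decoys": self.in_region_decoys,
            "outside_decoys": self.outside_decoys,
            "risk_gene": self.risk_gene,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: GroundTruth
    genome: dict[str, str]
    peak_sets: dict[str, RegionSet]  # keys: dhs, h3k27ac, and one per TF
    snps: list[SNPVariant]
    genes: list[GeneAnnotation]
    pwms: list[PWMModel]
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    clinical: list[SurvivalRecord]

    @property
    def tf_peak_sets(self) -> dict[str, RegionSet]:
        return {tf: self.peak_sets[tf] for tf in TF_NAMES}


def _dominant_prob_for_info(length: int, target_bits: float) -> float:
    """Dominant-base probability giving ~target_bits total information."""

    def info(d: float) -> float:
        rest = (1 - d) / 3
        per = d * math.log2(d / 0.25) + 3 * rest * math.log2(max(rest, 1e-12) / 0.25)
        return length * per

    lo, hi = 0.2501, 0.999999
    if info(hi) < target_bits:
        return hi
    for _ in range(60):
        mid = (lo + hi) / 2
        if info(mid) < target_bits:
            lo = mid
        else:
            hi = mid
    return hi


def make_planted_pwm(
    tf_name: str, rng: np.random.Generator, length: int = 8, info_bits: float = 14.0
) -> PWMModel:
    """A high-information PWM with a random consensus.

    The detection threshold is placed midway between the consensus score and
    the score after a single worst-case core substitution, so a one-base
    core change crosses the threshold by construction.
    """
    d = _dominant_prob_for_info(length, info_bits)
    rest = (1 - d) / 3
    consensus_idx = rng.integers(0, 4, size=length)
    probs = np.full((length, 4), rest)
    probs[np.arange(length), consensus_idx] = d
    contrib_hit = math.log2(d / 0.25)
    contrib_miss = math.log2(max(rest, 1e-3) / 0.25)
    consensus_score = length * contrib_hit
    mismatch_score = consensus_score - contrib_hit + contrib_miss
    threshold = (consensus_score + mismatch_score) / 2
    return PWMModel(tf_name, probs, threshold)


def _random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _idx_to_str(idx: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[idx].tobytes().decode()


def _random_peaks(
    rng: np.random.Generator,
    chrom: str,
    length: int,
    n: int,
    width_range: tuple[int, int],
    label: str,
) -> list[GenomicInterval]:
    widths = rng.integers(width_range[0], width_range[1] + 1, size=n)
    starts = rng.integers(0, length - width_range[1] - 1, size=n)
    return [
        GenomicInterval(chrom, int(s), int(s + w), label)
        for s, w in zip(starts, widths)
    ]


def simulate_regions_and_snps(
    config: SimulationConfig,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[dict[str, RegionSet], list[SNPVariant], dict[str, str], list[PWMModel], GroundTruth]:
    """Peak sets, SNP manifest, reference genome and planted PWMs.

    Planted SNPs are placed inside a constructed DHS ∩ H3K27ac ∩ TF triple
    overlap with the assigned TF's consensus written into the genome under
    allele A and the worst core base as allele B.  Decoys are placed inside
    regulatory regions (random flank, no planted motif) and outside all
    regulatory regions.
    """
    rngs = rngs or config.streams()
    rng_m, rng_g, rng_p, rng_s = (
        rngs["motifs"],
        rngs["genome"],
        rngs["peaks"],
        rngs["snps"],
    )
    chroms = sorted(config.chrom_lengths)

    pwms = [
        make_planted_pwm(tf, rng_m, config.motif_length, config.motif_info_bits)
        for tf in TF_NAMES
    ]
    genome_idx = {c: _random_sequence(rng_g, config.chrom_lengths[c]) for c in chroms}

    peak_lists: dict[str, list[GenomicInterval]] = {"dhs": [], "h3k27ac": []}
    for tf in TF_NAMES:
        peak_lists[tf] = []
    for c in chroms:
        L = config.chrom_lengths[c]
        peak_lists["dhs"] += _random_peaks(
            rng_p, c, L, config.n_dhs_peaks, (500, 1500), "DHS"
        )
        peak_lists["h3k27ac"] += _random_peaks(
            rng_p, c, L, config.n_mark_peaks, (500, 1500), "H3K27ac"
        )
        for tf in TF_NAMES:
            peak_lists[tf] += _random_peaks(
                rng_p, c, L, config.n_tf_peaks, (200, 400), tf
            )

    # planted sites: explicit triple overlap around each planted SNP
    truth = GroundTruth()
    core = config.motif_length // 2  # motif position holding the SNP base
    planted_pos: list[tuple[str, int]] = []
    margin = 30_000
    for i in range(config.n_planted):
        c = chroms[i % len(chroms)]
        L = config.chrom_lengths[c]
        while True:
            p = int(rng_s.integers(margin, L - margin))
            if all(cc != c or abs(p - pp) > 60_000 for cc, pp in planted_pos):
                break
        planted_pos.append((c, p))
        tf = TF_NAMES[i % len(TF_NAMES)]
        pwm = pwms[TF_NAMES.index(tf)]
        peak_lists["dhs"].append(GenomicInterval(c, p - 400, p + 400, "DHS"))
        peak_lists["h3k27ac"].append(GenomicInterval(c, p - 350, p + 450, "H3K27ac"))
        peak_lists[tf].append(GenomicInterval(c, p - 150, p + 150, tf))
        # write the consensus into the reference so allele A matches the motif
        cons = pwm.consensus()
        p0 = p - 1  # 0-based SNP position
        start = p0 - core
        for j, b in enumerate(cons):
            genome_idx[c][start + j] = BASES.index(b)
        snp_id = f"rsP{i + 1:04d}"
        truth.planted.append(
            PlantedEffect(
                snp_id=snp_id,
                tf=tf,
                target_gene="",  # filled by the gene layout below
                eqtl_beta=config.eqtl_beta,
                motif_core_offset=-core,
                de_direction=0,
                is_risk_gene=False,
            )
        )

    peak_sets = {name: RegionSet(ivs) for name, ivs in peak_lists.items()}

    # regulatory regions as the pipeline will compute them
    active = merge_intervals(
        RegionSet(peak_sets["dhs"].intervals + peak_sets["h3k27ac"].intervals)
    )
    tf_union = union_tf_peaks([peak_sets[tf] for tf in TF_NAMES])
    regulatory = intersect_regions(tf_union, active)

    genome = {c: _idx_to_str(genome_idx[c]) for c in chroms}

    snps: list[SNPVariant] = []
    for eff, (c, p) in zip(truth.planted, planted_pos):
        pwm = pwms[TF_NAMES.index(eff.tf)]
        cons = pwm.consensus()
        allele_a = cons[core]
        allele_b = BASES[int(pwm.probs[core].argmin())]
        snp = SNPVariant(eff.snp_id, c, p, allele_a, allele_b)
        # construction check: the intact allele carries a detectable motif
        flank = genome[c][p - 1 - config.flank : p + config.flank]
        ctx = SNPContext(snp, flank)
        assert allele_effect(pwm, ctx).call == "disrupt", (
            f"planted motif at {eff.snp_id} failed to score above threshold"
        )
        snps.append(snp)

    def ref_alleles(c: str, p: int) -> tuple[str, str]:
        a = genome[c][p - 1]
        b = BASES[(BASES.index(a) + 1 + int(rng_s.integers(0, 3))) % 4]
        return a, b

    # in-region decoys: uniform positions inside regulatory regions, away
    # from planted motifs
    reg_ivs = regulatory.intervals
    planted_exclusion = {
        (c, q) for c, p in planted_pos for q in range(p - 40, p + 41)
    }
    k = 0
    attempts = 0
    while k < config.n_in_region_decoys and attempts < 100_000:
        attempts += 1
        iv = reg_ivs[int(rng_s.integers(0, len(reg_ivs)))]
        pos0 = int(rng_s.integers(iv.start, iv.end))
        p = pos0 + 1
        if (iv.chrom, p) in planted_exclusion:
            continue
        a, b = ref_alleles(iv.chrom, p)
        snp_id = f"rsR{k + 1:04d}"
        snps.append(SNPVariant(snp_id, iv.chrom, p, a, b))
        truth.in_region_decoys.append(snp_id)
        k += 1

    # outside decoys: rejection-sample positions not in any regulatory region
    n_outside = config.n_snps - len(snps)
    k = 0
    attempts = 0
    while k < n_outside and attempts < 1_000_000:
        attempts += 1
        c = chroms[int(rng_s.integers(0, len(chroms)))]
        p = int(rng_s.integers(config.flank + 1, config.chrom_lengths[c] - config.flank))
        hit = snps_in_regions(
            [SNPVariant("probe", c, p, "A", "C")], regulatory
        )
        if hit:
            continue
        a, b = ref_alleles(c, p)
        snp_id = f"rsO{k + 1:04d}"
        snps.append(SNPVariant(snp_id, c, p, a, b))
        truth.outside_decoys.append(snp_id)
        k += 1

    return peak_sets, snps, genome, pwms, truth


def _layout_genes(
    config: SimulationConfig,
    snps: Sequence[SNPVariant],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[GeneAnnotation]:
    """Gene TSS layout: one target gene within the cis window of each planted
    SNP, the rest uniform across the genome."""
    chroms = sorted(config.chrom_lengths)
    snp_by_id = {s.snp_id: s for s in snps}
    genes: list[GeneAnnotation] = []
    for i, eff in enumerate(truth.planted):
        snp = snp_by_id[eff.snp_id]
        offset = int(rng.integers(2_000, 20_000)) * (1 if rng.random() < 0.5 else -1)
        tss = max(1, min(config.chrom_lengths[snp.chrom] - 1, snp.pos + offset))
        gid = f"GP{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(gid, snp.chrom, tss, strand))
        eff.target_gene = gid
    n_rest = config.n_genes - len(genes)
    for j in range(n_rest):
        c = chroms[int(rng.integers(0, len(chroms)))]
        tss = int(rng.integers(1, config.chrom_lengths[c]))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneAnnotation(f"G{j + 1:04d}", c, tss, strand))
    return genes


def simulate_genotypes(
    config: SimulationConfig,
    snps: Sequence[SNPVariant] | None = None,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotype calls for tumor samples.

    Per SNP the allele-B frequency is drawn uniformly from ``maf_range``
    (``planted_maf_range`` for planted SNPs so all three genotype classes are
    populated), then genotypes follow (p^2, 2pq, q^2).
    """
    rng = rng or config.streams()["genotypes"]
    if snps is None:
        snps = [
            SNPVariant(f"rs{i + 1:04d}", "chr1", i + 1, "A", "C")
            for i in range(config.n_snps)
        ]
    planted = set(truth.planted_snp_ids) if truth else set()
    samples = [f"T{i + 1:04d}" for i in range(config.n_tumor)]
    lo, hi = config.maf_range
    plo, phi = config.planted_maf_range
    data = {}
    for snp in snps:
        q = rng.uniform(plo, phi) if snp.snp_id in planted else rng.uniform(lo, hi)
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        data[snp.snp_id] = rng.choice([0, 1, 2], size=config.n_tumor, p=probs)
    calls = pd.DataFrame(data, index=samples, dtype=float)
    return GenotypeMatrix(calls)


def simulate_expression(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    truth: GroundTruth,
    genes: Sequence[GeneAnnotation] | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Normalized positive expression with planted cis effects.

    Values are generated on a log scale (baseline per gene ~ N(3, 0.7), noise
    N(0, noise_sd)) and exponentiated.  For planted SNP-gene pairs, tumor
    values gain ``eqtl_beta * noise_sd`` per allele-B copy on the log scale;
    planted DE genes gain a tumor-wide shift of log(de_fold) in the assigned
    direction.  Normal samples carry no genotype or DE effect.
    """
    rng = rng or config.streams()["expression"]
    if genes is None:
        genes = [
            GeneAnnotation(f"G{j + 1:04d}", "chr1", j + 1) for j in range(config.n_genes)
        ]
    tumor = list(genotypes.sample_ids)
    normal = [f"N{i + 1:04d}" for i in range(config.n_normal)]
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(3.0, 0.7, size=len(gene_ids))
    logvals = np.empty((len(gene_ids), len(tumor) + len(normal)))
    logvals[:] = baseline[:, None]
    logvals += rng.normal(0.0, config.noise_sd, size=logvals.shape)

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    n_t = len(tumor)
    for eff in truth.planted:
        row = gene_row[eff.target_gene]
        g = genotypes.calls[eff.snp_id].to_numpy(dtype=float)
        logvals[row, :n_t] += eff.eqtl_beta * config.noise_sd * g
        if eff.de_direction:
            logvals[row, :n_t] += eff.de_direction * math.log(config.de_fold)
    values = pd.DataFrame(np.exp(logvals), index=gene_ids, columns=tumor + normal)
    sample_class = pd.Series(
        ["tumor"] * n_t + ["normal"] * len(normal), index=tumor + normal
    )
    return ExpressionMatrix(values, sample_class)


def simulate_survival(
    config: SimulationConfig,
    expression: ExpressionMatrix,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> list[SurvivalRecord]:
    """Exponential recurrence times with elevated hazard in the high tail.

    Tumors whose expression of the designated risk gene exceeds the normal
    mean get hazard ``base_hazard * hazard_ratio``; others ``base_hazard``.
    A ``censor_rate`` fraction of samples is censored at a uniform time
    before their event.
    """
    rng = rng or config.streams()["survival"]
    tumor = expression.samples_of_class("tumor")
    normal = expression.samples_of_class("normal")
    risk_gene = truth.risk_gene
    hazard = np.full(len(tumor), config.base_hazard)
    if risk_gene is not None and risk_gene in expression.values.index:
        tv = expression.values.loc[risk_gene, tumor].to_numpy(dtype=float)
        mu = expression.values.loc[risk_gene, normal].to_numpy(dtype=float).mean()
        hazard[tv > mu] *= config.hazard_ratio
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(tumor)) < config.censor_rate
    u = rng.random(len(tumor))
    records = []
    for i, s in enumerate(tumor):
        if censored[i]:
            records.append(SurvivalRecord(s, float(t_event[i] * u[i]), False))
        else:
            records.append(SurvivalRecord(s, float(t_event[i]), True))
    return records


def simulate_all(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate every pipeline input; optionally write all files to out_dir."""
    rngs = config.streams()
    peak_sets, snps, genome, pwms, truth = simulate_regions_and_snps(config, rngs)
    genes = _layout_genes(config, snps, truth, rngs["genes"])
    # planted DE shifts (alternating direction); the risk gene carries no DE
    # shift so both expression strata stay populated relative to normals
    for i, eff in enumerate(truth.planted[1:], start=1):
        eff.de_direction = 1 if i % 2 == 0 else -1
    truth.planted[0].is_risk_gene = True
    truth.risk_gene = truth.planted[0].target_gene

    genotypes = simulate_genotypes(config, snps, truth, rngs["genotypes"])
    expression = simulate_expression(config, genotypes, truth, genes, rngs["expression"])
    clinical = simulate_survival(config, expression, truth, rngs["survival"])

    ds = SyntheticDataset(
        config=config,
        truth=truth,
        genome=genome,
        peak_sets=peak_sets,
        snps=snps,
        genes=genes,
        pwms=pwms,
        genotypes=genotypes,
        expression=expression,
        clinical=clinical,
    )
    if out_dir is not None:
        write_dataset(ds, out_dir)
    return ds


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact in the pipeline's file dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def bed(name: str, rs: RegionSet) -> None:
        p = out / f"{name}.bed"
        write_bed(merge_intervals(rs), p)
        paths[name] = p

    bed("dhs", ds.peak_sets["dhs"])
    bed("h3k27ac", ds.peak_sets["h3k27ac"])
    for tf in TF_NAMES:
        bed(f"tf_{tf}", ds.peak_sets[tf])

    paths["snps"] = out / "snps.tsv"
    write_snp_manifest(ds.snps, paths["snps"])

    paths["genotypes"] = out / "genotypes.tsv"
    gt = ds.genotypes.calls.astype(int)
    gt.index.name = "sample_id"
    gt.to_csv(paths["genotypes"], sep="\t")

    paths["expression"] = out / "expression.tsv"
    ev = ds.expression.values.copy()
    ev.index.name = "gene_id"
    ev.to_csv(paths["expression"], sep="\t", float_format="%.6f")

    paths["classes"] = out / "sample_classes.tsv"
    cls = ds.expression.sample_class.rename("class")
    cls.index.name = "sample_id"
    cls.to_csv(paths["classes"], sep="\t")

    paths["genes"] = out / "genes.tsv"
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in ds.genes],
            "chrom": [g.chrom for g in ds.genes],
            "tss": [g.tss for g in ds.genes],
            "strand": [g.strand for g in ds.genes],
        }
    ).to_csv(paths["genes"], sep="\t", index=False)

    paths["clinical"] = out / "clinical.tsv"
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in ds.clinical],
            "time_months": [f"{r.time:.4f}" for r in ds.clinical],
            "event": [int(r.event) for r in ds.clinical],
        }
    ).to_csv(paths["clinical"], sep="\t", index=False)

    paths["fasta"] = out / "genome.fa"
    with open(paths["fasta"], "w") as fh:
        for c in sorted(ds.genome):
            fh.write(f">{c}\n")
            seq = ds.genome[c]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")

    paths["motifs"] = out / "motifs.txt"
    write_motif_file(ds.pwms, paths["motifs"])

    paths["truth"] = out / "truth.json"
    ds.truth.to_json(paths["truth"])
    return paths
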