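"""Genomic interval algebra for building tissue-specific regulatory regions.

Regulatory regions are defined as the base-pair intersection of (a) the union
of per-transcription-factor ChIP-seq peak sets and (b) open-chromatin /
active-enhancer regions (DNase hypersensitive sites unioned with H3K27ac
peaks).  SNPs from an array manifest are then filtered to those falling
inside a regulatory region.

Coordinate conventions: all intervals are BED-style 0-based half-open
``[start, end)``; SNP positions are 1-based (array-manifest style) and the
overlap test converts with ``pos - 1``.  Chromosome names are matched by
exact string equality; :func:`check_chrom_naming` reports mixed naming styles
rather than normalizing silently.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "SNPVariant",
    "RegionHit",
    "merge_intervals",
    "union_tf_peaks",
    "intersect_regions",
    "snps_in_regions",
    "annotate_tf_support",
    "check_chrom_naming",
    "read_bed",
    "write_bed",
    "read_snp_manifest",
    "write_snp_manifest",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom`` (0-based)."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"interval has empty chromosome name: {self!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval (need 0 <= start < end): "
                f"{self.chrom}:[{self.start},{self.end}) label={self.label!r}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass
class RegionSet:
    """A collection of intervals, optionally sorted/merged with per-interval
    support counts (number of distinct contributing TF peak sets)."""

    intervals: list[GenomicInterval] = field(default_factory=list)
    support_count: list[int] | None = None
    is_sorted: bool = False

    def __post_init__(self) -> None:
        if self.support_count is not None and len(self.support_count) != len(
            self.intervals
        ):
            raise ValueError("support_count length must match intervals")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


@dataclass(frozen=True)
class SNPVariant:
    """Array SNP: identifier, chromosome, 1-based position and two alleles."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: position must be >= 1")
        for al in (self.allele_a, self.allele_b):
            if al not in _VALID_BASES:
                raise ValueError(f"SNP {self.snp_id}: invalid allele {al!r}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"SNP {self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class RegionHit:
    """A SNP together with the merged regulatory region containing it."""

    snp: SNPVariant
    region: GenomicInterval
    support_count: int = 1


def _validated(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    out = []
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            iv = GenomicInterval(*iv)
        out.append(iv)
    return out


def merge_intervals(peaks: RegionSet | Iterable[GenomicInterval]) -> RegionSet:
    """Sort and merge overlapping or abutting intervals into maximal runs.

    The output covers exactly the union of input base pairs; abutting
    intervals (``end == start``) are merged into one region.
    """
    ivs = _validated(peaks.intervals if isinstance(peaks, RegionSet) else peaks)
    ivs.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.label)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.label))
    return RegionSet(merged, support_count=[1] * len(merged), is_sorted=True)


def union_tf_peaks(tf_peak_sets: Sequence[RegionSet]) -> RegionSet:
    """Union of all TF peak sets with per-region distinct-source support.

    Each merged output region is annotated with ``support_count`` = number of
    distinct input TF sets overlapping it by at least 1 bp anywhere in the
    region ("bound by one or more TFs" is a per-region criterion).
    """
    all_ivs: list[GenomicInterval] = []
    for rs in tf_peak_sets:
        all_ivs.extend(_validated(rs.intervals))
    merged = merge_intervals(RegionSet(all_ivs))
    # per merged region, count distinct source sets with >=1 bp overlap
    merged_sets = [merge_intervals(rs) for rs in tf_peak_sets]
    support = [0] * len(merged)
    for src in merged_sets:
        by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in src.intervals:
            starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)
        for i, region in enumerate(merged.intervals):
            se = by_chrom.get(region.chrom)
            if se is None:
                continue
            starts, ends = se
            # first source interval with end > region.start; overlap iff its
            # start < region.end (both lists are sorted and disjoint)
            j = bisect.bisect_right(starts, region.start)
            if j > 0 and ends[j - 1] > region.start:
                support[i] += 1
            elif j < len(starts) and starts[j] < region.end:
                support[i] += 1
    merged.support_count = support
    return merged


def intersect_regions(tf_regions: RegionSet, active_regions: RegionSet) -> RegionSet:
    """Base-pair intersection of two merged region sets (two-pointer sweep)."""
    a = merge_intervals(tf_regions)
    b = merge_intervals(active_regions)
    out: list[GenomicInterval] = []
    chroms = sorted(a.chroms() & b.chroms())
    a_by = {c: [iv for iv in a.intervals if iv.chrom == c] for c in chroms}
    b_by = {c: [iv for iv in b.intervals if iv.chrom == c] for c in chroms}
    for c in chroms:
        xs, ys = a_by[c], b_by[c]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(c, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return RegionSet(out, support_count=[1] * len(out), is_sorted=True)


def snps_in_regions(
    snps: Sequence[SNPVariant], regions: RegionSet
) -> list[RegionHit]:
    """Filter SNPs to those inside a merged region; input order preserved.

    A SNP at 1-based position ``pos`` is inside ``[start, end)`` iff
    ``start <= pos - 1 < end``.  SNPs on chromosomes absent from ``regions``
    are simply dropped.
    """
    merged = regions if regions.is_sorted else merge_intervals(regions)
    by_chrom: dict[str, tuple[list[int], list[GenomicInterval], list[int]]] = {}
    supports = merged.support_count or [1] * len(merged.intervals)
    for iv, sup in zip(merged.intervals, supports):
        starts, ivs, sups = by_chrom.setdefault(iv.chrom, ([], [], []))
        starts.append(iv.start)
        ivs.append(iv)
        sups.append(sup)
    hits: list[RegionHit] = []
    for snp in snps:
        entry = by_chrom.get(snp.chrom)
        if entry is None:
            continue
        starts, ivs, sups = entry
        pos0 = snp.pos - 1
        j = bisect.bisect_right(starts, pos0) - 1
        if j >= 0 and ivs[j].start <= pos0 < ivs[j].end:
            hits.append(RegionHit(snp, ivs[j], sups[j]))
    return hits


def annotate_tf_support(
    regions: RegionSet, tf_sets: dict[str, RegionSet]
) -> list[list[str]]:
    """For each region, the names of TF peak sets overlapping it by >= 1 bp."""
    names: list[list[str]] = [[] for _ in regions.intervals]
    for tf, rs in tf_sets.items():
        merged = merge_intervals(rs)
        hits = {
            id(iv)
            for iv in _overlapping(regions, merged)
        }
        for i, iv in enumerate(regions.intervals):
            if id(iv) in hits:
                names[i].append(tf)
    return names


def _overlapping(regions: RegionSet, other: RegionSet) -> list[GenomicInterval]:
    """Regions from `regions` overlapping any interval of merged set `other`."""
    out = []
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for iv in other.intervals:
        starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
    for iv in regions.intervals:
        se = by_chrom.get(iv.chrom)
        if se is None:
            continue
        starts, ends = se
        j = bisect.bisect_right(starts, iv.start)
        if (j > 0 and ends[j - 1] > iv.start) or (
            j < len(starts) and starts[j] < iv.end
        ):
            out.append(iv)
    return out


def check_chrom_naming(*sets: RegionSet) -> None:
    """Raise if chromosome names mix 'chrN' and bare 'N' styles."""
    names: set[str] = set()
    for rs in sets:
        names |= rs.chroms()
    prefixed = {n for n in names if n.startswith("chr")}
    bare = names - prefixed
    if prefixed and bare:
        raise ValueError(
            "mixed chromosome naming styles detected: "
            f"prefixed={sorted(prefixed)[:3]}... bare={sorted(bare)[:3]}...; "
            "harmonize inputs explicitly (no silent normalization is applied)"
        )


# ---------------------------------------------------------------------------
# I/O: plain BED3+ and SNP manifest TSV

def read_bed(path: str | Path, label: str = "") -> RegionSet:
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line has < 3 columns")
            name = fields[3] if len(fields) > 3 else label
            try:
                ivs.append(
                    GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return RegionSet(ivs)


def write_bed(regions: RegionSet, path: str | Path) -> None:
    supports = regions.support_count or [1] * len(regions.intervals)
    with open(path, "w") as fh:
        for iv, sup in zip(regions.intervals, supports):
            name = iv.label or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{sup}\n")


def read_snp_manifest(path: str | Path) -> list[SNPVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos", "allele_a", "allele_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SNP manifest missing columns {sorted(missing)}")
    return [
        SNPVariant(str(r.snp_id), str(r.chrom), int(r.pos), r.allele_a, r.allele_b)
        for r in df.itertuples()
    ]


def write_snp_manifest(snps: Sequence[SNPVariant], path: str | Path) -> None:
    pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "allele_a": [s.allele_a for s in snps],
            "allele_b": [s.allele_b for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)
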