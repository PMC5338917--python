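"""Independent brute-force oracles used to validate the implementation.

Each oracle deliberately takes the slowest, most literal route (per-base
membership sets, exhaustive enumeration, risk-set counting) so that it
shares no code path with the package.
"""

from __future__ import annotations

import math
from collections import defaultdict


# ---------------------------------------------------------------------------
# interval algebra: per-base membership

def per_base_cover(intervals) -> dict[str, set[int]]:
    """Every covered base, per chromosome."""
    cover: dict[str, set[int]] = defaultdict(set)
    for iv in intervals:
        cover[iv.chrom].update(range(iv.start, iv.end))
    return {c: s for c, s in cover.items() if s}


def runs_from_cover(cover: dict[str, set[int]]):
    """Maximal (chrom, start, end) runs reconstructed from a base set."""
    runs = []
    for chrom in sorted(cover):
        bases = sorted(cover[chrom])
        start = prev = bases[0]
        for b in bases[1:]:
            if b != prev + 1:
                runs.append((chrom, start, prev + 1))
                start = b
            prev = b
        runs.append((chrom, start, prev + 1))
    return runs


def per_base_source_support(tf_sets) -> dict[tuple[str, int], set[int]]:
    """Base -> set of source-set indices covering it."""
    support: dict[tuple[str, int], set[int]] = defaultdict(set)
    for si, rs in enumerate(tf_sets):
        for iv in rs:
            for b in range(iv.start, iv.end):
                support[(iv.chrom, b)].add(si)
    return support


def snp_scan(snps, intervals):
    """O(n*m) membership scan: SNPs whose 0-based position is covered."""
    kept = []
    for snp in snps:
        pos0 = snp.pos - 1
        if any(iv.chrom == snp.chrom and iv.start <= pos0 < iv.end for iv in intervals):
            kept.append(snp.snp_id)
    return kept


# ---------------------------------------------------------------------------
# one-way ANOVA from plain-Python sums of squares

def anova_hand(groups):
    """(F, dfb, dfw) via literal sums of squares on Python floats."""
    groups = [list(map(float, g)) for g in groups]
    n = sum(len(g) for g in groups)
    k = len(groups)
    grand = sum(sum(g) for g in groups) / n
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum(sum((x - m) ** 2 for x in g) for g, m in zip(groups, means))
    return (ssb / (k - 1)) / (ssw / (n - k)), k - 1, n - k


# ---------------------------------------------------------------------------
# exhaustive PWM scoring

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def score_hand(probs, seq, floor=1e-3, background=0.25):
    total = 0.0
    for i, b in enumerate(seq):
        if b == "N":
            total += min(
                math.log2(max(probs[i][j], floor) / background) for j in range(4)
            )
        else:
            total += math.log2(max(probs[i][_IDX[b]], floor) / background)
    return total


def best_placement_hand(probs, flank_seq, center_index, allele):
    """Exhaustive (offset, strand) enumeration; returns (score, offset, strand)."""
    L = len(probs)
    seq = flank_seq[:center_index] + allele + flank_seq[center_index + 1 :]
    best = None
    for offset in range(-(L - 1), 1):
        window = seq[center_index + offset : center_index + offset + L]
        rc = "".join(_COMP[b] for b in reversed(window))
        for strand, w in (("+", window), ("-", rc)):
            s = score_hand(probs, w)
            if best is None or s > best[0]:
                best = (s, offset, strand)
    return best


# ---------------------------------------------------------------------------
# product-limit estimator by risk-set counting

def km_hand(times, events):
    """[(t, S(t))] at each distinct event time, literal risk-set counts."""
    pairs = sorted(zip(times, events))
    distinct = sorted({t for t, e in pairs if e})
    s = 1.0
    curve = []
    for t in distinct:
        at_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, e in pairs if ti == t and e)
        s *= 1.0 - d / at_risk
        curve.append((t, s))
    return curve
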