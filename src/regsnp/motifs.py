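"""Allele-specific PWM scoring of SNP flanking sequence.

For a SNP with flanking sequence of ±F bp (default F = 20), every placement
of a length-L motif window that covers the SNP base is scored on both
strands, separately for each allele substituted at the center.  A motif
match is a window whose summed log2-odds score (base probability over a
uniform background) reaches the PWM's detection threshold.  Comparing the
per-allele best scores against the threshold classifies the SNP as
disrupting a motif, creating one, or neither.

The motif file dialect is HOMER-style: a header line ``>CONSENSUS<tab>NAME
<tab>THRESHOLD`` followed by L rows of four whitespace-separated base
probabilities in A C G T order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import SNPVariant

__all__ = [
    "PWMModel",
    "SNPContext",
    "AlleleEffectResult",
    "parse_motif_file",
    "write_motif_file",
    "score_window",
    "best_allele_score",
    "allele_effect",
    "scan_snps_for_motif_change",
    "motif_change_snp_ids",
    "reverse_complement",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: floor applied to matrix probabilities before the log, keeping scores finite
PROB_FLOOR = 1e-3

#: default minimum |score difference| (bits) to call a direction when both
#: alleles score above the detection threshold
DELTA_MIN_DEFAULT = 2.0


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWMModel:
    """Position probability matrix with a log2-odds detection threshold."""

    tf_name: str
    probs: np.ndarray  # (L, 4) in A C G T order
    threshold: float
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.tf_name}: probs must be (L>=1, 4)")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"PWM {self.tf_name}: position {bad} probabilities sum to "
                f"{sums[bad]:.6f}, outside 1 +/- 1e-3"
            )
        self.probs = self.probs / sums[:, None]
        if not np.isfinite(self.threshold):
            raise ValueError(f"PWM {self.tf_name}: threshold must be finite")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def score_matrix(self) -> np.ndarray:
        """(L, 4) matrix of per-base log2-odds contributions."""
        return np.log2(np.maximum(self.probs, PROB_FLOOR) / self.background)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    def information_bits(self) -> float:
        p = np.maximum(self.probs, 1e-12)
        return float((p * np.log2(p / self.background)).sum())


@dataclass
class SNPContext:
    """SNP plus its flanking sequence of 2F+1 bases centered on the SNP."""

    snp: SNPVariant
    flank: str

    def __post_init__(self) -> None:
        self.flank = self.flank.upper()
        if len(self.flank) % 2 != 1:
            raise ValueError(f"SNP {self.snp.snp_id}: flank length must be odd")
        bad = set(self.flank) - set("ACGTN")
        if bad:
            raise ValueError(f"SNP {self.snp.snp_id}: invalid bases {bad}")
        center = self.flank[self.center_index]
        if center not in (self.snp.allele_a, self.snp.allele_b):
            raise ValueError(
                f"SNP {self.snp.snp_id}: center base {center!r} matches neither allele"
            )

    @property
    def center_index(self) -> int:
        return len(self.flank) // 2

    def with_allele(self, allele: str) -> str:
        if allele not in (self.snp.allele_a, self.snp.allele_b):
            raise ValueError(
                f"SNP {self.snp.snp_id}: {allele!r} is not one of its alleles"
            )
        i = self.center_index
        return self.flank[:i] + allele + self.flank[i + 1 :]


@dataclass
class AlleleEffectResult:
    """Best per-allele motif scores and the resulting disrupt/create call."""

    snp_id: str
    tf_name: str
    best_score_a: float
    best_score_b: float
    best_offset_a: int
    best_strand_a: str
    best_offset_b: int
    best_strand_b: str
    delta: float
    call: str  # disrupt | create | neutral | none


def parse_motif_file(path: str | Path) -> list[PWMModel]:
    """Parse a HOMER-style motif file into PWM models.

    Probabilities off by more than 1e-3 from summing to 1, wrong row counts
    or non-numeric entries are rejected with the offending line number.
    """
    models: list[PWMModel] = []
    header: tuple[str, float] | None = None
    rows: list[list[float]] = []
    header_line = 0

    def flush(at_line: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        name, thr = header
        if not rows:
            raise ValueError(f"{path}:{header_line}: motif {name!r} has no matrix rows")
        try:
            models.append(PWMModel(name, np.array(rows), thr))
        except ValueError as exc:
            raise ValueError(f"{path}:{header_line}: {exc}") from exc
        header, rows = None, []

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(ln)
                fields = line[1:].split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{ln}: motif header needs consensus, name, threshold"
                    )
                try:
                    thr = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{ln}: non-numeric threshold {fields[2]!r}"
                    ) from exc
                header = (fields[1], thr)
                header_line = ln
            else:
                if header is None:
                    raise ValueError(f"{path}:{ln}: matrix row before any '>' header")
                vals = line.split()
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}:{ln}: expected 4 probabilities, got {len(vals)}"
                    )
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: non-numeric entry") from exc
    flush(-1)
    return models


def write_motif_file(models: Iterable[PWMModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(f">{m.consensus()}\t{m.tf_name}\t{m.threshold:.6f}\n")
            for row in m.probs:
                fh.write("\t".join(f"{p:.6f}" for p in row) + "\n")


def score_window(pwm: PWMModel, seq: str) -> float:
    """Summed log2-odds score of one length-L window.

    An N base contributes the minimum over the four bases at that position
    (conservative: never inflates a match).
    """
    seq = seq.upper()
    if len(seq) != pwm.length:
        raise ValueError(
            f"sequence length {len(seq)} != PWM length {pwm.length} ({pwm.tf_name})"
        )
    sm = pwm.score_matrix()
    total = 0.0
    for i, b in enumerate(seq):
        if b == "N":
            total += float(sm[i].min())
        else:
            total += float(sm[i, _BASE_IDX[b]])
    return total


def best_allele_score(
    pwm: PWMModel, ctx: SNPContext, allele: str
) -> tuple[float, int, str]:
    """Best score over all motif placements covering the SNP base, both strands.

    The center base of the context is substituted with ``allele``; every
    start offset in ``[-(L-1), 0]`` relative to the SNP is scored on the
    forward sequence and on its reverse complement (same PWM).  Ties are
    broken by smallest offset, then by the + strand.
    """
    L = pwm.length
    F = ctx.center_index
    if F < L - 1:
        raise ValueError(
            f"flank of {F} bp cannot fit all placements of a {L}-bp motif; "
            f"extract at least +/-{L - 1} bp around the SNP"
        )
    seq = ctx.with_allele(allele)
    best: tuple[float, int, str] | None = None
    for offset in range(-(L - 1), 1):
        window = seq[F + offset : F + offset + L]
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            s = score_window(pwm, w)
            if best is None or s > best[0]:
                best = (s, offset, strand)
    assert best is not None
    return best


def allele_effect(
    pwm: PWMModel, ctx: SNPContext, delta_min: float = DELTA_MIN_DEFAULT
) -> AlleleEffectResult:
    """Classify the SNP's effect on this motif.

    - ``disrupt``: allele A reaches the detection threshold, allele B does not
      (or both pass and A scores higher by at least ``delta_min`` bits);
    - ``create``: the mirror image (B gains the match);
    - ``neutral``: both pass with |delta| < delta_min;
    - ``none``: neither allele reaches the threshold.
    """
    sa, offa, stra = best_allele_score(pwm, ctx, ctx.snp.allele_a)
    sb, offb, strb = best_allele_score(pwm, ctx, ctx.snp.allele_b)
    delta = sa - sb
    thr = pwm.threshold
    if sa >= thr and sb < thr:
        call = "disrupt"
    elif sb >= thr and sa < thr:
        call = "create"
    elif sa < thr and sb < thr:
        call = "none"
    elif abs(delta) < delta_min:
        call = "neutral"
    else:
        call = "disrupt" if delta > 0 else "create"
    return AlleleEffectResult(
        snp_id=ctx.snp.snp_id,
        tf_name=pwm.tf_name,
        best_score_a=sa,
        best_score_b=sb,
        best_offset_a=offa,
        best_strand_a=stra,
        best_offset_b=offb,
        best_strand_b=strb,
        delta=delta,
        call=call,
    )


def scan_snps_for_motif_change(
    contexts: Sequence[SNPContext],
    pwms: Sequence[PWMModel],
    delta_min: float = DELTA_MIN_DEFAULT,
) -> list[AlleleEffectResult]:
    """Evaluate every SNP x PWM combination; order follows the inputs."""
    return [
        allele_effect(pwm, ctx, delta_min=delta_min)
        for ctx in contexts
        for pwm in pwms
    ]


def motif_change_snp_ids(results: Iterable[AlleleEffectResult]) -> list[str]:
    """SNPs with at least one disrupt/create call, in first-seen order."""
    seen: dict[str, None] = {}
    for r in results:
        if r.call in ("disrupt", "create") and r.snp_id not in seen:
            seen[r.snp_id] = None
    return list(seen)
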