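"""PWM parsing and allele-specific scoring vs exhaustive enumeration."""

import numpy as np
import pytest

from regsnp.intervals import SNPVariant
from regsnp.motifs import (
    PWMModel,
    SNPContext,
    parse_motif_file,
    write_motif_file,
    score_window,
    best_allele_score,
    allele_effect,
    scan_snps_for_motif_change,
    motif_change_snp_ids,
    reverse_complement,
    BASES,
)
from regsnp.simulate import make_planted_pwm
from _oracles import score_hand, best_placement_hand


def random_pwm(rng, length=None, name="TF"):
    L = length or int(rng.integers(1, 12))
    probs = rng.dirichlet(np.ones(4), size=L)
    return PWMModel(name, probs, threshold=float(rng.uniform(-5, 10)))


def random_context(rng, flank=20, alleles=("A", "G")):
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=2 * flank + 1))
    seq = seq[:flank] + alleles[0] + seq[flank + 1 :]
    snp = SNPVariant("rs1", "chr1", 500, alleles[0], alleles[1])
    return SNPContext(snp, seq)


class TestParseMotifFile:
    def test_uniform_single_position_motif(self, tmp_path):
        p = tmp_path / "m.motifs"
        p.write_text(">N\tflat\t0\n0.25 0.25 0.25 0.25\n")
        (m,) = parse_motif_file(p)
        assert m.length == 1 and m.threshold == 0.0
        assert score_window(m, "C") == 0.0

    def test_two_motifs_names_preserved(self, tmp_path):
        p = tmp_path / "m.motifs"
        p.write_text(
            ">A\tfirst\t1.5\n1 0 0 0\n>CG\tsecond\t2\n0 1 0 0\n0 0 1 0\n"
        )
        models = parse_motif_file(p)
        assert [m.tf_name for m in models] == ["first", "second"]
        assert [m.length for m in models] == [1, 2]

    def test_bad_row_and_bad_sum_rejected_with_line(self, tmp_path):
        p = tmp_path / "m.motifs"
        p.write_text(">A\tbad\t0\n0.5 0.5\n")
        with pytest.raises(ValueError, match=":2"):
            parse_motif_file(p)
        p.write_text(">A\tbad\t0\n0.9 0.4 0.1 0.1\n")
        with pytest.raises(ValueError, match="sum"):
            parse_motif_file(p)

    def test_round_trip_identity(self, tmp_path, rng):
        models = [random_pwm(rng, name=f"TF{i}") for i in range(5)]
        p = tmp_path / "rt.motifs"
        write_motif_file(models, p)
        back = parse_motif_file(p)
        for a, b in zip(models, back):
            assert a.tf_name == b.tf_name
            assert b.threshold == pytest.approx(a.threshold, abs=1e-6)
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-5)


class TestScoreWindow:
    def test_uniform_pwm_scores_zero(self, rng):
        m = PWMModel("flat", np.full((6, 4), 0.25), 0.0)
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=6))
        assert score_window(m, seq) == 0.0

    def test_single_position_log_ratio(self):
        m = PWMModel("one", np.array([[0.5, 0.25, 0.125, 0.125]]), 0.0)
        assert score_window(m, "A") == pytest.approx(1.0)
        assert score_window(m, "C") == pytest.approx(0.0)
        assert score_window(m, "G") == pytest.approx(-1.0)

    def test_n_scores_as_worst_base(self):
        m = PWMModel("one", np.array([[0.5, 0.25, 0.125, 0.125]]), 0.0)
        assert score_window(m, "N") == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="length"):
            score_window(random_pwm(rng, length=4), "ACT")

    def test_matches_per_position_oracle(self, rng):
        for _ in range(30):
            m = random_pwm(rng)
            seq = "".join(
                "ACGTN"[i] for i in rng.integers(0, 5, size=m.length)
            )
            assert score_window(m, seq) == pytest.approx(
                score_hand(m.probs, seq), rel=1e-12, abs=1e-12
            )

    def test_monotone_in_observed_base_probability(self, rng):
        m = random_pwm(rng, length=5)
        seq = "ACGTA"
        base_score = score_window(m, seq)
        probs = m.probs.copy()
        i, b = 2, seq[2]
        j = BASES.index(b)
        probs[i] = probs[i] * 0.5
        probs[i, j] += 0.5  # raise observed base, renormalized by construction
        probs[i] /= probs[i].sum()
        boosted = PWMModel("up", probs, m.threshold)
        assert score_window(boosted, seq) >= base_score


class TestBestAlleleScore:
    def test_length_one_motif_two_placements_at_snp(self):
        m = PWMModel("one", np.array([[0.7, 0.1, 0.1, 0.1]]), 0.0)
        ctx = random_context(np.random.default_rng(0), flank=3)
        score, offset, strand = best_allele_score(m, ctx, "A")
        # only the SNP base itself can be scored; A matches the consensus
        assert offset == 0
        assert strand == "+"
        assert score == pytest.approx(np.log2(0.7 / 0.25))

    def test_flank_too_short_raises(self, rng):
        m = random_pwm(rng, length=8)
        ctx = random_context(rng, flank=5)
        with pytest.raises(ValueError, match="flank"):
            best_allele_score(m, ctx, ctx.snp.allele_a)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        for _ in range(40):
            m = random_pwm(rng, length=int(rng.integers(1, 10)))
            ctx = random_context(rng)
            for allele in (ctx.snp.allele_a, ctx.snp.allele_b):
                got = best_allele_score(m, ctx, allele)
                want = best_placement_hand(
                    m.probs, ctx.flank, ctx.center_index, allele
                )
                assert got[0] == pytest.approx(want[0], rel=1e-12, abs=1e-12)

    def test_reverse_complement_swaps_strands_preserves_scores(self, rng):
        for _ in range(20):
            m = random_pwm(rng, length=int(rng.integers(1, 9)))
            ctx = random_context(rng)
            a = ctx.snp.allele_a
            rc_snp = SNPVariant(
                "rs1rc", "chr1", 500,
                reverse_complement(ctx.snp.allele_a),
                reverse_complement(ctx.snp.allele_b),
            )
            rc_ctx = SNPContext(rc_snp, reverse_complement(ctx.flank))
            s_fwd, _, strand_fwd = best_allele_score(m, ctx, a)
            s_rc, _, strand_rc = best_allele_score(
                m, rc_ctx, reverse_complement(a)
            )
            assert s_rc == pytest.approx(s_fwd, rel=1e-12, abs=1e-12)


class TestAlleleEffect:
    def planted_case(self, rng):
        pwm = make_planted_pwm("TF", rng)
        cons = pwm.consensus()
        core = pwm.length // 2
        flank = 20
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=2 * flank + 1))
        seq = seq[: flank - core] + cons + seq[flank - core + pwm.length :]
        allele_a = cons[core]
        allele_b = BASES[int(pwm.probs[core].argmin())]
        snp = SNPVariant("rsX", "chr1", 500, allele_a, allele_b)
        return pwm, SNPContext(snp, seq)

    def test_planted_consensus_break_called_disrupt(self, rng):
        pwm, ctx = self.planted_case(rng)
        res = allele_effect(pwm, ctx)
        assert res.call == "disrupt"
        assert res.best_score_a >= pwm.threshold > res.best_score_b
        assert res.delta > 0

    def test_background_mostly_none(self, rng):
        pwm = make_planted_pwm("TF", rng)
        calls = [
            allele_effect(pwm, random_context(rng)).call for _ in range(100)
        ]
        assert calls.count("none") >= 95

    def test_equal_scores_is_neutral_or_none(self):
        m = PWMModel("flat", np.full((3, 4), 0.25), 5.0)
        ctx = random_context(np.random.default_rng(1))
        res = allele_effect(m, ctx)
        assert res.delta == 0.0
        assert res.call in ("neutral", "none")


class TestScan:
    def test_empty_pwm_list(self, rng):
        assert scan_snps_for_motif_change([random_context(rng)], []) == []

    def test_pwm_order_invariance(self, rng):
        pwms = [random_pwm(rng, name=f"T{i}") for i in range(4)]
        ctxs = [random_context(rng) for _ in range(10)]
        a = scan_snps_for_motif_change(ctxs, pwms)
        b = scan_snps_for_motif_change(ctxs, pwms[::-1])
        key = lambda r: (r.snp_id, r.tf_name)
        assert sorted(
            [(r.snp_id, r.tf_name, r.call, r.delta) for r in a]
        ) == sorted([(r.snp_id, r.tf_name, r.call, r.delta) for r in b])

    def test_planted_disruptions_recovered_few_false_flags(self, rng):
        pwm = make_planted_pwm("TF", rng)
        contexts, planted_ids = [], []
        for i in range(100):
            if i < 10:
                p, ctx = TestAlleleEffect().planted_case(rng)
                ctx = SNPContext(
                    SNPVariant(f"rs{i}", "chr1", 500, ctx.snp.allele_a,
                               ctx.snp.allele_b),
                    ctx.flank,
                )
                contexts.append((p, ctx))
                planted_ids.append(f"rs{i}")
            else:
                ctx = random_context(rng)
                ctx = SNPContext(
                    SNPVariant(f"rs{i}", "chr1", 500, ctx.snp.allele_a,
                               ctx.snp.allele_b),
                    ctx.flank,
                )
                contexts.append((pwm, ctx))
        results = [allele_effect(p, c) for p, c in contexts]
        flagged = set(motif_change_snp_ids(results))
        assert set(planted_ids) <= flagged
        assert len(flagged - set(planted_ids)) <= 2
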