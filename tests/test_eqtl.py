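"""cis-eQTL scan: ANOVA correctness, windows, FDR and scan invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regsnp.intervals import SNPVariant
from regsnp.eqtl import (
    GeneAnnotation,
    GenotypeMatrix,
    ExpressionMatrix,
    drop_silent_genes,
    genes_near_snp,
    anova_eqtl,
    run_eqtl_scan,
)
from _oracles import anova_hand


def make_expr(values: np.ndarray, gene_ids, sample_ids, classes):
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df, pd.Series(classes, index=sample_ids))


class TestDropSilentGenes:
    def test_all_zero_gene_removed_single_nonzero_kept(self):
        vals = np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.0], [1.0, 2.0, 3.0]])
        expr = make_expr(vals, ["g0", "g1", "g2"], ["s1", "s2", "s3"],
                         ["tumor"] * 3)
        out = drop_silent_genes(expr)
        assert out.gene_ids == ["g1", "g2"]

    def test_planted_zero_rows_all_removed(self, rng):
        vals = rng.uniform(0.1, 5, size=(30, 10))
        zero_rows = rng.choice(30, size=7, replace=False)
        vals[zero_rows] = 0.0
        expr = make_expr(vals, [f"g{i}" for i in range(30)],
                         [f"s{i}" for i in range(10)], ["tumor"] * 10)
        out = drop_silent_genes(expr)
        assert len(out.gene_ids) == 23
        assert set(out.gene_ids) == {f"g{i}" for i in range(30) if i not in zero_rows}


class TestGenesNearSnp:
    snp = SNPVariant("rs1", "chr1", 100_000, "A", "G")

    def gene(self, gid, tss, chrom="chr1"):
        return GeneAnnotation(gid, chrom, tss)

    def test_tss_at_snp_distance_zero(self):
        near = genes_near_snp(self.snp, [self.gene("g", 100_000)])
        assert [g.gene_id for g in near] == ["g"]

    def test_window_boundary_inclusive(self):
        got = genes_near_snp(
            self.snp,
            [self.gene("in", 125_000), self.gene("out", 125_001)],
            window=25_000,
        )
        assert [g.gene_id for g in got] == ["in"]

    def test_matches_exhaustive_filter_and_ordering(self, rng):
        genes = [
            self.gene(f"g{i}", int(rng.integers(1, 200_000)),
                      "chr1" if rng.random() < 0.8 else "chr2")
            for i in range(300)
        ]
        got = genes_near_snp(self.snp, genes, window=25_000)
        expect = [
            g for g in genes
            if g.chrom == "chr1" and abs(g.tss - self.snp.pos) <= 25_000
        ]
        expect.sort(key=lambda g: (abs(g.tss - self.snp.pos), g.gene_id))
        assert [g.gene_id for g in got] == [g.gene_id for g in expect]


class TestAnovaEqtl:
    def test_identical_groups_f_zero(self):
        res = anova_eqtl([0] * 3 + [1] * 3 + [2] * 3, [1, 2, 3] * 3)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0

    def test_hand_worked_example_f27(self):
        res = anova_eqtl(
            [0, 0, 0, 1, 1, 1, 2, 2, 2], [1, 2, 3, 4, 5, 6, 7, 8, 9]
        )
        assert res.f_stat == pytest.approx(27.0, abs=1e-12)
        # df (2, 6): p matches the F(2,6) upper tail
        assert res.p_value == pytest.approx(stats.f.sf(27.0, 2, 6), rel=1e-12)
        assert res.group_sizes == {0: 3, 1: 3, 2: 3}
        assert res.group_means == {0: 2.0, 1: 5.0, 2: 8.0}

    def test_matches_hand_and_scipy_on_random_inputs(self, rng):
        for _ in range(50):
            sizes = rng.integers(3, 20, size=3)
            groups = [rng.normal(rng.uniform(-1, 1), 1, size=s) for s in sizes]
            g = np.concatenate([[i] * s for i, s in enumerate(sizes)])
            x = np.concatenate(groups)
            res = anova_eqtl(g, x)
            f_hand, dfb, dfw = anova_hand(groups)
            f_sp, p_sp = stats.f_oneway(*groups)
            assert res.f_stat == pytest.approx(f_hand, rel=1e-10)
            assert res.f_stat == pytest.approx(f_sp, rel=1e-10)
            assert res.p_value == pytest.approx(p_sp, rel=1e-8)

    def test_missing_genotypes_excluded_pairwise(self):
        g = [0, 0, 0, np.nan, 1, 1, 1, 2, 2, 2]
        x = [1, 2, 3, 99, 4, 5, 6, 7, 8, 9]
        res = anova_eqtl(g, x)
        assert res.f_stat == pytest.approx(27.0, abs=1e-12)

    def test_small_groups_dropped_then_untestable(self):
        # the 2-copy class has < 3 samples -> dropped; still 2 groups left
        res = anova_eqtl([0, 0, 0, 1, 1, 1, 2], [1, 2, 3, 4, 5, 6, 7])
        assert res.testable
        assert 2 not in {k for k, v in res.group_sizes.items() if v >= 3}
        # only one eligible group -> untestable, no crash
        res2 = anova_eqtl([0, 0, 0, 1, 1], [1, 2, 3, 4, 5])
        assert not res2.testable
        assert res2.p_value is None

    def test_zero_within_variance_unequal_means_p_zero(self):
        res = anova_eqtl([0, 0, 0, 1, 1, 1], [5, 5, 5, 9, 9, 9])
        assert res.f_stat == np.inf
        assert res.p_value == 0.0


class TestRunEqtlScan:
    def build(self, rng, n=120, n_snps=10, planted_snp=0, beta=0.0):
        samples = [f"s{i}" for i in range(n)]
        snp_ids = [f"rs{i}" for i in range(n_snps)]
        snps = [
            SNPVariant(sid, "chr1", 50_000 + 1_000 * i, "A", "G")
            for i, sid in enumerate(snp_ids)
        ]
        calls = pd.DataFrame(
            rng.choice([0, 1, 2], size=(n, n_snps), p=[0.49, 0.42, 0.09]),
            index=samples, columns=snp_ids, dtype=float,
        )
        genes = [GeneAnnotation(f"g{i}", "chr1", 50_000 + 1_000 * i) for i in range(n_snps)]
        vals = rng.lognormal(1.0, 0.5, size=(n_snps, n))
        vals[planted_snp] *= np.exp(
            beta * calls[snp_ids[planted_snp]].to_numpy()
        )
        expr = make_expr(vals, [g.gene_id for g in genes], samples, ["tumor"] * n)
        return snps, GenotypeMatrix(calls), expr, genes

    def test_empty_inputs_give_empty_results(self, rng):
        snps, gt, expr, genes = self.build(rng)
        assert run_eqtl_scan([], gt, expr, genes) == []
        assert run_eqtl_scan(snps, gt, expr, []) == []

    def test_no_overlapping_samples_is_config_error(self, rng):
        snps, gt, expr, genes = self.build(rng)
        other = ExpressionMatrix(
            expr.values.rename(columns=lambda s: "x" + s),
            pd.Series("tumor", index=["x" + s for s in expr.sample_ids]),
        )
        with pytest.raises(ValueError, match="no overlapping tumor samples"):
            run_eqtl_scan(snps, gt, other, genes)

    def test_planted_effect_ranked_first(self, rng):
        snps, gt, expr, genes = self.build(rng, n=200, n_snps=50, planted_snp=7,
                                           beta=1.5)
        results = run_eqtl_scan(snps, gt, expr, genes)
        best = min((r for r in results if r.testable), key=lambda r: r.p_value)
        assert best.snp_id == "rs7"
        assert best.significant

    def test_sample_permutation_invariance(self, rng):
        snps, gt, expr, genes = self.build(rng, n=80, n_snps=5)
        ref = run_eqtl_scan(snps, gt, expr, genes)
        perm = rng.permutation(expr.sample_ids).tolist()
        expr_p = ExpressionMatrix(expr.values[perm], expr.sample_class)
        got = run_eqtl_scan(snps, gt, expr_p, genes)
        for a, b in zip(ref, got):
            assert (a.snp_id, a.gene_id) == (b.snp_id, b.gene_id)
            assert a.p_value == pytest.approx(b.p_value, rel=1e-10, abs=1e-300)

    def test_null_scan_at_fdr_makes_no_discoveries(self, rng):
        snps, gt, expr, genes = self.build(rng, n=150, n_snps=40, beta=0.0)
        results = run_eqtl_scan(snps, gt, expr, genes, fdr=0.05)
        assert sum(r.significant for r in results) <= 2
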