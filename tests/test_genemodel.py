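"""Gene models: exon collapse, offsets, profiles, categorisation, bias."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mnsbs.genemodel import (
    AlignedRead,
    GeneModel,
    assignment_rate,
    categorize_reads,
    classify_gene_bias,
    collapse_exons,
    exonic_offset,
    gene_flank_counts,
    gene_length_gc,
    positional_profile,
    pseudobulk_logfc,
)


def entries(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chrom", "strand", "start", "end"]
    )


class TestCollapseExons:
    def test_overlapping_union(self):
        df = entries(
            [("g", "g", "chr1", "+", 100, 200), ("g", "g", "chr1", "+", 150, 250)]
        )
        (m,) = collapse_exons(df)
        assert m.exons == [(100, 250)] and m.length == 150

    def test_disjoint_unchanged(self):
        df = entries(
            [("g", "g", "chr1", "+", 0, 100), ("g", "g", "chr1", "+", 200, 300)]
        )
        (m,) = collapse_exons(df)
        assert m.exons == [(0, 100), (200, 300)]

    def test_idempotent(self):
        df = entries(
            [("g", "g", "chr1", "+", 0, 150), ("g", "g", "chr1", "+", 100, 300)]
        )
        (m1,) = collapse_exons(df)
        again = entries(
            [("g", "g", "chr1", "+", s, e) for s, e in m1.exons]
        )
        (m2,) = collapse_exons(again)
        assert m1.exons == m2.exons

    def test_multi_chrom_gene_skipped(self):
        df = entries(
            [("g", "g", "chr1", "+", 0, 100), ("g", "g", "chr2", "+", 0, 100)]
        )
        with pytest.warns(UserWarning):
            assert collapse_exons(df) == []

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(1000):
            n = int(rng.integers(1, 8))
            rows = []
            bitmap = np.zeros(500, dtype=bool)
            for _ in range(n):
                s = int(rng.integers(0, 450))
                e = s + int(rng.integers(1, 50))
                rows.append(("g", "g", "chr1", "+", s, e))
                bitmap[s:e] = True
            (m,) = collapse_exons(entries(rows))
            assert m.length == int(bitmap.sum())
            rebuilt = np.zeros(500, dtype=bool)
            for s, e in m.exons:
                rebuilt[s:e] = True
            assert (rebuilt == bitmap).all()


class TestLengthGC:
    @pytest.mark.parametrize(
        "seq,exons,gc,length",
        [
            ("GGCC", [(0, 4)], 1.0, 4),
            ("AATT", [(0, 4)], 0.0, 4),
            ("GCAT", [(0, 2), (2, 4)], 0.5, 4),
        ],
    )
    def test_examples(self, seq, exons, gc, length):
        m = GeneModel("g", "c", "+", exons)
        got_len, got_gc = gene_length_gc(m, {"c": seq})
        assert (got_len, got_gc) == (length, gc)

    def test_ambiguous_bases_excluded(self):
        m = GeneModel("g", "c", "+", [(0, 4)])
        _, gc = gene_length_gc(m, {"c": "GNNC"})
        assert gc == 1.0

    def test_out_of_contig_errors(self):
        m = GeneModel("g", "c", "+", [(0, 10)])
        with pytest.raises(ValueError):
            gene_length_gc(m, {"c": "ACGT"})


class TestExonicOffset:
    def test_plus_strand_start(self):
        m = GeneModel("g", "c", "+", [(0, 1000)])
        assert exonic_offset(m, 0) == 0.0

    def test_minus_strand_symmetry(self):
        m = GeneModel("g", "c", "-", [(0, 1000)])
        assert exonic_offset(m, 999) == 0.0
        assert exonic_offset(m, 0) == pytest.approx(999 / 1000)

    def test_spliced_cumulative(self):
        m = GeneModel("g", "c", "+", [(0, 100), (200, 300)])
        assert exonic_offset(m, 200) == pytest.approx(0.5)

    def test_intronic_position_errors(self):
        m = GeneModel("g", "c", "+", [(0, 100), (200, 300)])
        with pytest.raises(ValueError):
            exonic_offset(m, 150)


def _read(rid, chrom, strand, start, end, **kw):
    return AlignedRead(rid, chrom, strand, [(start, end)], **kw)


class TestPositionalProfile:
    def test_five_prime_terminal_reads_in_bin_zero(self):
        m = GeneModel("g", "c", "+", [(0, 1000)])
        reads = [
            _read(f"r{i}", "c", "+", 0, 90, assigned_gene="g") for i in range(50)
        ]
        p5, p3 = positional_profile(reads, [m], sample_fraction=1.0, seed=0)
        assert p5.bins[0] == pytest.approx(1.0)
        assert p5.bins[1:].sum() == 0
        # read 3' ends at base 89 -> one-past offset 0.09 -> bin 9, never bin 0
        assert p3.bins[0] == 0

    def test_terminal_read_lands_in_bin_100(self):
        m = GeneModel("g", "c", "+", [(0, 1000)])
        reads = [_read("r", "c", "+", 910, 1000, assigned_gene="g")]
        _, p3 = positional_profile(reads, [m], sample_fraction=1.0, seed=0)
        assert p3.bins[100] == pytest.approx(1.0)

    def test_per_gene_weight_is_one(self):
        a = GeneModel("a", "c", "+", [(0, 1000)])
        b = GeneModel("b", "c", "+", [(5000, 6000)])
        reads = [
            _read(f"r{i}", "c", "+", 10 * i, 10 * i + 90, assigned_gene="a")
            for i in range(80)
        ] + [_read("s", "c", "+", 5000, 5090, assigned_gene="b")]
        p5, _ = positional_profile(reads, [a, b], sample_fraction=1.0, seed=0)
        assert p5.bins.sum() == pytest.approx(2.0)
        assert p5.n_genes == 2

    def test_uniform_placement_flat(self):
        m = GeneModel("g", "c", "+", [(0, 100_000)])
        rng = np.random.default_rng(5)
        # 5' ends uniform over the whole gene body
        starts = rng.integers(0, 100_000, size=100_000)
        reads = [
            _read(f"r{i}", "c", "+", int(s), int(s) + 90, assigned_gene="g")
            for i, s in enumerate(starts)
        ]
        p5, _ = positional_profile(reads, [m], sample_fraction=1.0, seed=0)
        assert p5.bins[100] == 0  # offset 1.0 unreachable for 5' ends
        counts = p5.bins[:100] * len(reads)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert stats.chi2.sf(chi2, df=99) > 0.01

    def test_filters_multimappers_and_missing_tags(self):
        m = GeneModel("g", "c", "+", [(0, 1000)])
        reads = [
            _read("a", "c", "+", 0, 90, assigned_gene="g", n_hits=2),
            _read("b", "c", "+", 0, 90, assigned_gene="g", has_cbc=False),
            _read("c", "c", "+", 0, 90, assigned_gene=None),
        ]
        p5, _ = positional_profile(reads, [m], sample_fraction=1.0, seed=0)
        assert p5.bins.sum() == 0


class TestCategorize:
    @pytest.fixture()
    def two_genes(self):
        return [
            GeneModel("a", "c", "+", [(0, 500)]),
            GeneModel("b", "c", "+", [(400, 900)]),  # overlaps a
            GeneModel("d", "c", "-", [(2000, 2500)]),
        ]

    def test_unique_sense_assignment(self, two_genes):
        out = categorize_reads([_read("r", "c", "+", 10, 100)], two_genes)
        assert out.assigned == 1 and out.per_gene["a"] == 1

    def test_ambiguous_counted_for_both_in_ambig_mode(self, two_genes):
        out = categorize_reads([_read("r", "c", "+", 420, 480)], two_genes)
        assert out.ambiguous == 1
        assert out.per_gene["a"] == 0
        assert out.per_gene_ambig["a"] == 1 and out.per_gene_ambig["b"] == 1

    def test_antisense_only_is_no_feature_in_sense_mode(self, two_genes):
        out = categorize_reads([_read("r", "c", "+", 2100, 2190)], two_genes)
        assert out.no_feature == 1
        out2 = categorize_reads([_read("r", "c", "+", 2100, 2190)], two_genes,
                                sense="antisense")
        assert out2.assigned == 1 and out2.per_gene["d"] == 1

    def test_multimapper_precedence(self, two_genes):
        out = categorize_reads([_read("r", "c", "+", 420, 480, n_hits=3)], two_genes)
        assert out.multimapping == 1 and out.ambiguous == 0
        assert out.per_gene_multi["a"] == 1 and out.per_gene_multi["b"] == 1

    def test_unmapped(self, two_genes):
        out = categorize_reads([AlignedRead("r", None, "+", [])], two_genes)
        assert out.unmapped == 1

    def test_partition_on_fixture(self, small_genome):
        from mnsbs.simulate import simulate_alignments

        _, _, models = small_genome
        reads, _ = simulate_alignments(
            models, seed=3, gap_fraction=0.05, multimap_fraction=0.1
        )
        out = categorize_reads(reads, models)
        assert out.total == len(reads)
        for g in out.per_gene:
            assert out.per_gene_ambig[g] >= out.per_gene[g]


class TestAssignmentRate:
    def test_examples(self):
        assert assignment_rate(90, 100) == 0.9
        assert assignment_rate(0, 50) == 0.0
        with pytest.raises(ZeroDivisionError):
            assignment_rate(0, 0)

    def test_flank_includes_downstream_reads(self):
        m = GeneModel("g", "c", "+", [(1000, 2000)])
        inside = [_read(f"i{k}", "c", "+", 1100, 1190) for k in range(9)]
        past_end = _read("p", "c", "+", 2050, 2140)  # 50 bp past gene end
        flank = gene_flank_counts(inside + [past_end], [m], flank=100)
        assert flank["g"] == 10
        assigned = categorize_reads(inside + [past_end], [m]).per_gene["g"]
        assert assigned == 9
        assert assignment_rate(assigned, flank["g"]) == 0.9


class TestClassifyBias:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "count_a", "count_b", "assigned_a", "flank_a",
                     "assigned_b", "flank_b"],
        )

    def test_identical_platforms_all_similar(self):
        rows = [(f"g{i}", 500, 500, 400, 500, 400, 500) for i in range(20)]
        recs = classify_gene_bias(self._frame(rows))
        assert all(r.count_class == "similar" for r in recs)
        assert all(r.assign_class == "none" for r in recs)

    def test_planted_fold_difference(self):
        rows = [(f"g{i}", 500, 500, 400, 500, 400, 500) for i in range(20)]
        rows.append(("hot", 600, 100, 80, 100, 80, 100))
        recs = {r.gene_id: r for r in classify_gene_bias(self._frame(rows))}
        # ln(601/101) = 1.784 > ln 5 after centring on the zero median
        assert recs["hot"].count_class == "higher_a"

    def test_low_count_genes_excluded(self):
        rows = [("tiny", 50, 40, 10, 20, 10, 20)]
        assert classify_gene_bias(self._frame(rows)) == []

    def test_assignment_bias_detected(self):
        rows = [(f"g{i}", 500, 500, 450, 500, 450, 500) for i in range(10)]
        rows.append(("biased", 500, 500, 450, 500, 100, 1000))  # 0.9 vs 0.1
        recs = {r.gene_id: r for r in classify_gene_bias(self._frame(rows))}
        assert recs["biased"].assign_class == "higher_a"


class TestPseudobulk:
    def test_identical_matrices_zero(self):
        a = pd.DataFrame(np.arange(12).reshape(3, 4) + 1,
                         columns=list("wxyz"))
        out = pseudobulk_logfc(a, a.copy())
        assert np.allclose(out["logfc"], 0)
        assert not out["de"].any()

    def test_boundary_not_flagged_under_strict_inequality(self):
        # gene at TPM 90 vs 40 -> logFC = ln(100/50) = ln 2 exactly
        a = pd.DataFrame([[90.0, 1e6 - 90.0]], columns=["g", "rest"])
        b = pd.DataFrame([[40.0, 1e6 - 40.0]], columns=["g", "rest"])
        out = pseudobulk_logfc(a, b)
        assert out.loc["g", "logfc"] == pytest.approx(np.log(2))
        assert not out.loc["g", "de"]

    def test_zero_gene_logfc_zero(self):
        a = pd.DataFrame([[0, 100]], columns=["z", "g"]).astype(float)
        b = pd.DataFrame([[0, 200]], columns=["z", "g"]).astype(float)
        out = pseudobulk_logfc(a, b)
        assert out.loc["z", "logfc"] == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pseudobulk_logfc(pd.DataFrame(), pd.DataFrame())
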