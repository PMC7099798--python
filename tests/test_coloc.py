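import itertools

import numpy as np
import pandas as pd
import pytest

from _oracles import fisher_twosided_enum, hypergeom_upper_tail_enum, pearson_manual, window_starts_enum
from imprintscape.coloc import (
    WindowCounts,
    build_windows,
    chromosome_enrichment,
    codistribution_correlation,
    codistribution_permutation_pvalue,
    count_in_windows,
    fisher_exact_2x2,
    ratio_profile,
)
from imprintscape.genome_io import GeneSet, GenomeAnnotation


def _make_counts(n_ref, n_a, n_b):
    n = len(n_ref)
    table = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": (np.arange(n) + 1) * 1000,
            "n_ref": n_ref,
            "n_a": n_a,
            "n_b": n_b,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        table["r_a"] = np.where(table.n_ref > 0, table.n_a / table.n_ref, np.nan)
        table["r_b"] = np.where(table.n_ref > 0, table.n_b / table.n_ref, np.nan)
    return WindowCounts(table=table, grid=None)


class TestBuildWindows:
    def test_exact_tiling(self):
        ann = GenomeAnnotation(
            chromosomes=[("chr1", 3_000_000)],
            genes=pd.DataFrame(
                {"gene_id": ["g"], "symbol": ["G"], "chrom": ["chr1"],
                 "start": [0], "end": [10], "strand": ["+"]}
            ),
        )
        grid = build_windows(ann, 1_000_000, 1_000_000)
        assert grid.windows[["start", "end"]].values.tolist() == [
            [0, 1_000_000], [1_000_000, 2_000_000], [2_000_000, 3_000_000],
        ]

    def test_last_window_truncated(self):
        ann = GenomeAnnotation(
            chromosomes=[("chr1", 2_500_000)],
            genes=pd.DataFrame(
                {"gene_id": ["g"], "symbol": ["G"], "chrom": ["chr1"],
                 "start": [0], "end": [10], "strand": ["+"]}
            ),
        )
        grid = build_windows(ann, 1_000_000, 1_000_000)
        assert grid.windows.iloc[-1][["start", "end"]].tolist() == [2_000_000, 2_500_000]

    def test_overlapping_windows_small_case(self):
        ann = GenomeAnnotation(
            chromosomes=[("chr1", 10)],
            genes=pd.DataFrame(
                {"gene_id": ["g"], "symbol": ["G"], "chrom": ["chr1"],
                 "start": [0], "end": [1], "strand": ["+"]}
            ),
        )
        grid = build_windows(ann, 4, 3)
        assert grid.windows[["start", "end"]].values.tolist() == [
            [0, 4], [3, 7], [6, 10], [9, 10],
        ]

    @pytest.mark.parametrize("length,step", [(10, 3), (100, 7), (1000, 1000), (999, 100)])
    def test_starts_match_enumeration(self, length, step):
        ann = GenomeAnnotation(
            chromosomes=[("chr1", length)],
            genes=pd.DataFrame(
                {"gene_id": ["g"], "symbol": ["G"], "chrom": ["chr1"],
                 "start": [0], "end": [1], "strand": ["+"]}
            ),
        )
        grid = build_windows(ann, step, step)
        assert grid.windows["start"].tolist() == window_starts_enum(length, step)

    def test_nonpositive_rejected(self, tiny_genome):
        with pytest.raises(ValueError):
            build_windows(tiny_genome, 0, 5)
        with pytest.raises(ValueError):
            build_windows(tiny_genome, 5, -1)


class TestCountInWindows:
    def test_half_open_assignment(self, tiny_genome):
        grid = build_windows(tiny_genome, 1_000_000, 1_000_000)
        counts = count_in_windows(grid, tiny_genome)
        chr1 = counts.table[counts.table.chrom == "chr1"]
        # genes at 10 and 999,999 share window 0; 1,000,000 opens window 1
        assert chr1["n_ref"].tolist() == [2, 1, 0]

    def test_full_set_saturates_ratio(self, tiny_genome, gene_set_factory):
        all_genes = gene_set_factory("all", tiny_genome.genes["symbol"])
        grid = build_windows(tiny_genome, 1_000_000, 1_000_000)
        counts = count_in_windows(grid, tiny_genome, set_a=all_genes)
        populated = counts.table[counts.table.n_ref > 0]
        assert (populated["r_a"] == 1.0).all()

    def test_count_conservation_nonoverlapping(self, random_genome):
        grid = build_windows(random_genome, 1_000_000, 1_000_000)
        counts = count_in_windows(grid, random_genome)
        assert counts.table["n_ref"].sum() == 50
        # direct membership scan per gene
        for _, win in counts.table.iterrows():
            manual = (
                (random_genome.genes["start"] >= win.start)
                & (random_genome.genes["start"] < win.start + grid.window)
            ).sum()
            assert manual == win.n_ref

    def test_overlapping_stride_counts_each_containing_window(self, random_genome):
        grid = build_windows(random_genome, 2_000_000, 1_000_000)
        counts = count_in_windows(grid, random_genome)
        for _, win in counts.table.iterrows():
            manual = (
                (random_genome.genes["start"] >= win.start)
                & (random_genome.genes["start"] < win.start + grid.window)
            ).sum()
            assert manual == win.n_ref

    def test_doubling_window_preserves_total(self, random_genome):
        small = count_in_windows(build_windows(random_genome, 1_000_000, 1_000_000), random_genome)
        big = count_in_windows(build_windows(random_genome, 2_000_000, 2_000_000), random_genome)
        assert small.table["n_ref"].sum() == big.table["n_ref"].sum() == 50
        assert (big.table["n_ref"] > 0).sum() <= (small.table["n_ref"] > 0).sum() * 2


class TestRatioProfile:
    def test_threshold_flag_inclusive(self):
        counts = _make_counts([4], [2], [0])
        prof = ratio_profile(counts, threshold=0.5)
        assert prof["ratio"].iloc[0] == 0.5
        assert bool(prof["above_threshold"].iloc[0])

    def test_empty_window_missing_ratio(self):
        counts = _make_counts([0], [0], [0])
        prof = ratio_profile(counts)
        assert np.isnan(prof["ratio"].iloc[0])
        assert pd.isna(prof["above_threshold"].iloc[0])

    def test_flags_from_direct_comparison(self):
        counts = _make_counts([10, 10], [1, 9], [0, 0])
        prof = ratio_profile(counts, threshold=0.5)
        assert prof["above_threshold"].tolist() == [False, True]


class TestCodistributionCorrelation:
    def test_log_shift_collinear(self):
        counts = _make_counts([10, 10, 10], [1, 2, 4], [2, 4, 8])
        res = codistribution_correlation(counts)
        assert res.r == pytest.approx(1.0)
        assert res.n_windows_used == 3

    def test_zero_variance_convention(self):
        counts = _make_counts([10, 10, 10], [1, 2, 4], [2, 2, 2])
        with pytest.warns(UserWarning, match="zero variance"):
            res = codistribution_correlation(counts)
        assert res.r == 0.0

    def test_matches_manual_pearson(self):
        rng = np.random.default_rng(3)
        n_ref = rng.integers(5, 50, 20)
        n_a = rng.integers(1, 5, 20)
        n_b = rng.integers(1, 5, 20)
        counts = _make_counts(n_ref, n_a, n_b)
        res = codistribution_correlation(counts)
        manual = pearson_manual(np.log10(n_a / n_ref), np.log10(n_b / n_ref))
        assert res.r == pytest.approx(manual, abs=1e-12)

    def test_symmetry_in_sets(self):
        rng = np.random.default_rng(4)
        n_ref = rng.integers(5, 50, 15)
        n_a = rng.integers(1, 5, 15)
        n_b = rng.integers(1, 5, 15)
        ab = codistribution_correlation(_make_counts(n_ref, n_a, n_b))
        ba = codistribution_correlation(_make_counts(n_ref, n_b, n_a))
        assert ab.r == pytest.approx(ba.r, abs=1e-14)

    def test_too_few_windows_names_filter(self):
        counts = _make_counts([10, 0, 0], [1, 0, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="n_ref>0, n_a>0 and n_b>0"):
            codistribution_correlation(counts)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_balanced_table_is_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_margins(self):
        """Every 2x2 table with all margins <= 12 agrees with full enumeration."""
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            if max(a + b, c + d, a + c, b + d) > 12:
                continue
            got = fisher_exact_2x2([[a, b], [c, d]])
            want = fisher_twosided_enum([[a, b], [c, d]])
            assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])


class TestChromosomeEnrichment:
    @staticmethod
    def _annotation(n_per_chrom):
        rows, k = [], 0
        for chrom, n in n_per_chrom.items():
            for i in range(n):
                rows.append((f"g{k}", f"S{k}", chrom, 1000 * i, 1000 * i + 500, "+"))
                k += 1
        genes = pd.DataFrame(
            rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]
        )
        return GenomeAnnotation(
            chromosomes=[(c, 10_000_000) for c in n_per_chrom], genes=genes
        )

    def test_tie_reported_up_with_upper_tail(self):
        ann = self._annotation({"chr1": 20, "chr2": 80})
        query = GeneSet(name="q", members=frozenset(
            [f"S{i}" for i in range(2)] + [f"S{i}" for i in range(20, 28)]
        ))  # x=2 on chr1: expected = 10*20/100 = 2
        row = chromosome_enrichment(ann, query).set_index("category").loc["1"]
        assert row["expected"] == pytest.approx(2.0)
        assert row["direction"] == "up"
        assert row["pvalue"] >= 0.5

    def test_doubled_upper_tail_matches_enumeration(self):
        ann = self._annotation({"chr1": 20, "chr2": 80})
        query = GeneSet(name="q", members=frozenset(
            [f"S{i}" for i in range(6)] + [f"S{i}" for i in range(20, 24)]
        ))  # x=6 of K=20, n=10, N=100
        row = chromosome_enrichment(ann, query).set_index("category").loc["1"]
        want = min(1.0, 2 * hypergeom_upper_tail_enum(100, 20, 10, 6))
        assert row["direction"] == "up"
        assert row["pvalue"] == pytest.approx(want, rel=1e-9)

    def test_query_all_genes_saturates(self):
        ann = self._annotation({"chr1": 20, "chr2": 80})
        query = GeneSet(name="q", members=frozenset(ann.genes["symbol"]))
        table = chromosome_enrichment(ann, query).set_index("category")
        for cat in ("1", "2"):
            assert table.loc[cat, "x"] == table.loc[cat, "K"]
            assert table.loc[cat, "pvalue"] == pytest.approx(1.0)

    def test_arm_level_needs_bands(self, tiny_genome, gene_set_factory):
        with pytest.raises(ValueError, match="CytoBandMap"):
            chromosome_enrichment(
                tiny_genome, gene_set_factory("q", ["A1"]), bands=None, level="arm"
            )


class TestPermutationPvalue:
    def test_same_seed_same_p(self, random_genome, gene_set_factory):
        syms = random_genome.genes["symbol"].tolist()
        a = gene_set_factory("a", syms[:20])
        b = gene_set_factory("b", syms[10:30])
        grid = build_windows(random_genome, 1_000_000, 1_000_000)
        r1 = codistribution_permutation_pvalue(random_genome, a, b, grid, n_perm=100, seed=9)
        r2 = codistribution_permutation_pvalue(random_genome, a, b, grid, n_perm=100, seed=9)
        assert r1.permutation_pvalue == r2.permutation_pvalue
        assert r1.r == r2.r

    def test_min_permutations_enforced(self, random_genome, gene_set_factory):
        syms = random_genome.genes["symbol"].tolist()
        a = gene_set_factory("a", syms[:20])
        grid = build_windows(random_genome, 1_000_000, 1_000_000)
        with pytest.raises(ValueError):
            codistribution_permutation_pvalue(random_genome, a, a, grid, n_perm=50, seed=1)
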