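import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imprintscape.de import (
    ModeratedTTest,
    de_count_matrix,
    de_screen,
    estimate_variance_prior,
    make_comparison_plan,
    moderated_t_fit,
)
from imprintscape.preprocess import ExpressionBundle


def _meta(regions, stages, hemispheres=("L",), per_cell=2):
    rows = []
    for r in regions:
        for s in stages:
            for h in hemispheres:
                for k in range(per_cell):
                    rows.append((f"{r}_s{s:02d}{h}{k}", r, s, h, f"D{s}{k}"))
    return pd.DataFrame(
        rows, columns=["sample", "region", "stage", "hemisphere", "donor"]
    ).set_index("sample")


class TestComparisonPlan:
    def test_enumerated_counts(self):
        meta = _meta(["HIP", "CBC"], [1, 2, 3])
        adjacent = make_comparison_plan(meta, mode="adjacent-stage")
        pairs = make_comparison_plan(meta, mode="region-pair")
        assert len(adjacent) == 2 * 2  # 2 regions x 2 consecutive stage pairs
        assert len(pairs) == 3 * 1  # 3 stages x C(2,2)

    def test_missing_stage_skips_its_comparisons(self):
        meta = _meta(["HIP", "CBC"], [1, 2, 3])
        meta = meta[~((meta.region == "HIP") & (meta.stage == 2))]
        adjacent = make_comparison_plan(meta, mode="adjacent-stage")
        labels = {c.label for c in adjacent}
        assert labels == {"CBC_L_stg1-stg2", "CBC_L_stg2-stg3"}

    def test_all_region_pairs_at_one_stage(self):
        from imprintscape.preprocess import REGION_VOCABULARY

        meta = _meta(REGION_VOCABULARY, [5])
        pairs = make_comparison_plan(meta, mode="region-pair")
        assert len(pairs) == 16 * 15 // 2  # 120, the all-pairs layout

    def test_region_pairs_pool_hemispheres(self):
        meta = _meta(["HIP", "CBC"], [1], hemispheres=("L", "R"), per_cell=1)
        (comp,) = make_comparison_plan(meta, mode="region-pair")
        assert len(comp.group1) == len(comp.group2) == 2

    def test_no_comparison_is_error(self):
        meta = _meta(["HIP"], [1])
        with pytest.raises(ValueError, match="no valid comparison"):
            make_comparison_plan(meta, mode="region-pair")


class TestVariancePrior:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(7)
        d0_true, s0_true, G, dg = 4.0, 2.0, 10_000, 8
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, G)
        s2 = sigma2 * rng.chisquare(dg, G) / dg
        prior = estimate_variance_prior(s2, dg)
        assert prior.d0 == pytest.approx(d0_true, rel=0.20)
        assert prior.s0sq == pytest.approx(s0_true, rel=0.10)

    def test_equal_variances_infinite_prior(self):
        s2 = np.full(100, 3.0)
        prior = estimate_variance_prior(s2, 1e9)
        assert np.isinf(prior.d0)
        assert prior.s0sq == pytest.approx(3.0, abs=1e-6)

    def test_minimal_input_smoke(self):
        rng = np.random.default_rng(8)
        prior = estimate_variance_prior(rng.chisquare(4, 10), 4)
        assert prior.d0 > 0 and prior.s0sq > 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_variance_prior(np.zeros(20), 4)


class TestModeratedT:
    def test_worked_example(self):
        X = np.array([[0.0], [2.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        est = ModeratedTTest(prior_df=2.0, prior_s2=1.0).fit(X, y)
        assert est.log2fc_[0] == pytest.approx(3.0)
        assert est.s2_pooled_[0] == pytest.approx(2.0)
        assert est.s2_post_[0] == pytest.approx(1.5)
        assert est.t_[0] == pytest.approx(3 / np.sqrt(1.5))
        # reference distribution has d_g + d0 = 4 degrees of freedom
        assert est.pvalue_[0] == pytest.approx(2 * stats.t.sf(3 / np.sqrt(1.5), 4))

    def test_zero_prior_reduces_to_ordinary_t(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 50))
        y = np.repeat([0, 1], 5)
        est = ModeratedTTest(prior_df=0.0).fit(X, y)
        t_ref, p_ref = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=True)
        np.testing.assert_allclose(est.t_, t_ref, atol=1e-10)
        np.testing.assert_allclose(est.pvalue_, p_ref, atol=1e-10)

    def test_infinite_prior_scaled_z(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(8, 30))
        y = np.repeat([0, 1], 4)
        s0sq = 0.7
        est = ModeratedTTest(prior_df=np.inf, prior_s2=s0sq).fit(X, y)
        lfc = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        expected = lfc / np.sqrt(s0sq * (1 / 4 + 1 / 4))
        np.testing.assert_allclose(est.t_, expected, atol=1e-10)
        np.testing.assert_allclose(est.pvalue_, 2 * stats.norm.sf(np.abs(expected)), atol=1e-12)

    def test_zero_variance_gene_flagged_undefined(self):
        X = np.zeros((8, 2))
        X[:, 1] = np.random.default_rng(1).normal(size=8)
        y = np.repeat([0, 1], 4)
        est = ModeratedTTest(prior_df=0.0).fit(X, y)
        assert np.isnan(est.t_[0]) and np.isnan(est.adj_pvalue_[0])
        assert np.isfinite(est.adj_pvalue_[1])

    def test_null_calibration_bh_any_discovery_rate(self):
        """With no true effects, BH at 0.05 yields any discovery in ~<=5% of runs."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            X = rng.normal(0, 0.5, size=(10, 2000))
            y = np.repeat([0, 1], 5)
            est = ModeratedTTest().fit(X, y)
            flags = est.decision(alpha=0.05, fc=1.0)  # p-criterion only
            hits += bool(flags.any())
        # binomial(100, 0.05) 99% upper bound
        assert hits <= 12


class TestScreenAndCounts:
    def _table(self, adj_p, lfc):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(adj_p))],
             "log2fc": lfc, "adj_pvalue": adj_p}
        )

    def test_boundary_rules(self):
        table, count = de_screen(self._table([0.04, 0.05], [1.0, 3.0]))
        # |FC| = 2 is included, adj.P = 0.05 is excluded
        assert table["pass"].tolist() == [True, False]
        assert count == 1

    def test_count_matches_row_scan(self):
        rng = np.random.default_rng(12)
        adj = rng.random(500)
        lfc = rng.normal(0, 1.5, 500)
        table, count = de_screen(self._table(adj, lfc), alpha=0.05, fc=2.0)
        naive = sum(1 for p, f in zip(adj, lfc) if p < 0.05 and abs(f) >= 1.0)
        assert count == naive

    def test_count_matrix_symmetric_and_planted_region_dominates(self):
        rng = np.random.default_rng(13)
        meta = _meta(["HIP", "CBC", "OFC"], [3], hemispheres=("L",), per_cell=5)
        genes = [f"g{i}" for i in range(300)]
        expr = pd.DataFrame(
            rng.normal(8, 0.4, (300, len(meta))), index=genes, columns=meta.index
        )
        # plant strong CBC-specific shifts in 30 genes
        cbc = meta.index[meta.region == "CBC"]
        expr.loc[genes[:30], cbc] += 3.0
        bundle = ExpressionBundle(expression=expr, meta=meta)
        plan = make_comparison_plan(meta, mode="region-pair")
        tables = moderated_t_fit(bundle, plan)
        mats, adjacent = de_count_matrix(tables, plan)
        mat = mats[3]
        pd.testing.assert_frame_equal(mat, mat.T)
        off_cbc = mat.loc["HIP", "OFC"]
        assert mat.loc["CBC", "HIP"] > off_cbc
        assert mat.loc["CBC", "OFC"] > off_cbc
        assert adjacent.empty

    def test_all_zero_when_nothing_passes(self):
        rng = np.random.default_rng(14)
        meta = _meta(["HIP", "CBC"], [3], per_cell=3)
        expr = pd.DataFrame(
            rng.normal(8, 0.4, (100, len(meta))),
            index=[f"g{i}" for i in range(100)], columns=meta.index,
        )
        bundle = ExpressionBundle(expression=expr, meta=meta)
        plan = make_comparison_plan(meta, mode="region-pair")
        tables = moderated_t_fit(bundle, plan)
        for t in tables.values():
            t["pass"] = False
        mats, _ = de_count_matrix(tables, plan)
        assert (mats[3].to_numpy() == 0).all()
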