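import anndata as ad
import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from ersecretome.gating import (
    balanced_subsample,
    differential_expression,
    filter_candidates,
    gate_er_stress_cells,
    groupwise_rank_test,
    normalize_expression,
    rank_test_pair,
    summarize_population,
)
from ersecretome.simulate import simulate_sc_counts


def _adata(counts, conditions=None, genes=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    obs = pd.DataFrame(
        {
            "condition": conditions if conditions is not None else ["MI"] * n,
            "cluster": pd.array([1] * n, dtype="Int64"),
        },
        index=[f"c{i}" for i in range(n)],
    )
    var = pd.DataFrame(index=genes if genes is not None else [f"g{j}" for j in range(g)])
    return ad.AnnData(X=counts.astype(float), obs=obs, var=var)


class TestNormalize:
    def test_depth_proportionality(self):
        adata = _adata([[10, 90], [20, 180]])
        norm = normalize_expression(adata)
        np.testing.assert_allclose(norm.X[0], norm.X[1])

    def test_equal_depth_unchanged_up_to_scale(self):
        adata = _adata([[10, 40], [30, 20]])
        norm = normalize_expression(adata)
        np.testing.assert_allclose(norm.X, adata.X)

    def test_all_zero_cell_dropped_with_warning(self, caplog):
        adata = _adata([[1, 2], [0, 0], [3, 4]])
        with caplog.at_level("WARNING", logger="ersecretome"):
            norm = normalize_expression(adata)
        assert norm.n_obs == 2
        assert any("all-zero" in r.message for r in caplog.records)


class TestGate:
    def test_zero_marker_everywhere_gates_nobody(self):
        adata = _adata([[0, 5], [0, 8]], genes=["m1", "g1"])
        res = gate_er_stress_cells(adata, ["m1"], threshold=1.0)
        assert res.n_gated == 0

    def test_fourfold_cell_is_member_at_threshold_one(self):
        # one cell at 4x the dataset mean of both markers: log2(4) = 2 > 1
        X = np.array([[40.0, 40.0], [8.0, 8.0], [8.0, 8.0], [8.0, 8.0]])
        adata = _adata(X, genes=["m1", "m2"])
        res = gate_er_stress_cells(adata, ["m1", "m2"], threshold=1.0)
        assert res.membership.tolist() == [True, False, False, False]

    def test_missing_marker_raises_listing_genes(self, sc_small):
        adata, _ = sc_small
        with pytest.raises(KeyError, match="NOPE"):
            gate_er_stress_cells(adata, ["Hspa5", "NOPE"])

    def test_threshold_monotonicity(self, sc_small):
        adata, truth = sc_small
        norm = normalize_expression(adata)
        sizes = [
            gate_er_stress_cells(norm, truth.marker_genes, thr).n_gated
            for thr in (0.0, 0.5, 1.0, 1.5, 2.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_composition_conserves_gated_total(self, sc_small):
        adata, truth = sc_small
        norm = normalize_expression(adata)
        res = gate_er_stress_cells(norm, truth.marker_genes, 1.0)
        per_condition = res.composition.groupby("condition")["n_gated"].sum()
        member_counts = res.membership.groupby(norm.obs["condition"].values).sum()
        for cond, total in per_condition.items():
            assert total == member_counts[cond]
        assert res.composition["n_gated"].sum() == res.n_gated

    def test_planted_subpopulation_recovered(self, sc_small):
        adata, truth = sc_small
        norm = normalize_expression(adata)
        res = gate_er_stress_cells(norm, truth.marker_genes, 1.0)
        recovered = 100 * res.n_gated / norm.n_obs
        planted = 100 * truth.subpop_mask.mean()
        assert abs(recovered - planted) <= 1.0


class TestSummarize:
    @pytest.mark.parametrize(
        "gated,total,expected",
        [(372, 11743, 3.2), (1100, 11743, 9.4), (0, 5000, 0.0)],
    )
    def test_percentages_to_one_decimal(self, gated, total, expected):
        assert summarize_population(gated, total) == expected

    def test_zero_total_is_missing(self):
        assert np.isnan(summarize_population(0, 0))

    def test_gated_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            summarize_population(10, 5)


class TestDifferentialExpression:
    def test_zero_gene_has_unit_fold_and_p_one(self):
        X = np.array([[0, 5], [0, 6], [0, 7], [0, 8.0]])
        adata = _adata(X)
        de = differential_expression(adata, np.array([True, True, False, False]),
                                     np.array([False, False, True, True]))
        assert de.loc["g0", "fold_change"] == 1.0
        assert de.loc["g0", "p_value"] == 1.0

    def test_overlapping_groups_rejected(self, sc_small):
        adata, _ = sc_small
        mask = np.zeros(adata.n_obs, bool)
        mask[:10] = True
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(adata, mask, mask)

    def test_swap_symmetry(self, sc_small):
        adata, truth = sc_small
        norm = normalize_expression(adata)
        a = truth.subpop_mask[:norm.n_obs]
        b = ~a
        de_ab = differential_expression(norm, a, b)
        de_ba = differential_expression(norm, b, a)
        np.testing.assert_allclose(de_ab["p_value"], de_ba["p_value"], atol=1e-12)
        # fold products equal 1 up to pseudocount effects
        prod = de_ab["fold_change"] * de_ba["fold_change"]
        assert np.quantile(np.abs(np.log2(prod)), 0.95) < 0.2

    def test_null_type_one_error_rate(self):
        # exchangeable null: same NB distribution in both groups
        rng = np.random.default_rng(21)
        X = rng.negative_binomial(5, 0.3, size=(400, 500)).astype(float)
        adata = _adata(X)
        groups = np.arange(400) < 200
        de = differential_expression(adata, groups, ~groups)
        frac = (de["p_value"] < 0.05).mean()
        assert 0.02 <= frac <= 0.08

    def test_planted_fold_detected_across_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = rng.gamma(4, 0.5, size=(400, 1))
            lam = np.tile(base, (1, 1))
            lam[200:] *= 3.0  # planted 3-fold up in group b
            X = rng.poisson(lam * 5).astype(float)
            adata = _adata(np.hstack([X, rng.poisson(2.0, size=(400, 1))]))
            groups = np.arange(400) < 200
            de = differential_expression(adata, groups, ~groups)
            filter_candidates(de)
            hits += bool(de.loc["g0", "passes_filters"])
        assert hits >= 19

    @pytest.mark.parametrize(
        "fold,p,mean_b,kept",
        [(1.6, 0.01, 0.2, True), (1.4, 0.001, 5.0, False), (1.6, 0.2, 5.0, False),
         (1.6, 0.01, 0.05, False)],
    )
    def test_filter_thresholds(self, fold, p, mean_b, kept):
        de = pd.DataFrame(
            {"mean_expr_a": [1.0], "mean_expr_b": [mean_b],
             "fold_change": [fold], "p_value": [p]},
            index=pd.Index(["g"], name="gene"),
        )
        assert (filter_candidates(de) == ["g"]) is kept

    def test_planted_enriched_genes_mostly_recovered(self):
        adata, truth = simulate_sc_counts(
            n_cells=1200, n_genes=400, enriched_gene_count=60, seed=3
        )
        norm = normalize_expression(adata)
        mask = truth.subpop_mask[: norm.n_obs]
        de = differential_expression(norm, ~mask, mask)  # b = gated population
        kept = set(filter_candidates(de))
        recovered = len(kept & set(truth.enriched_genes)) / len(truth.enriched_genes)
        assert recovered >= 0.9


class TestBalancedSubsample:
    def _three_groups(self):
        rng = np.random.default_rng(0)
        sizes = {"hs": 300, "mi": 120, "rz": 250}
        conds = sum([[k] * v for k, v in sizes.items()], [])
        X = rng.poisson(2, size=(len(conds), 20)).astype(float)
        return _adata(X, conditions=conds)

    def test_groups_equalized_to_target(self):
        adata = self._three_groups()
        out = balanced_subsample(adata, target_size=120, seed=1)
        assert out.obs["condition"].value_counts().tolist() == [120, 120, 120]

    def test_default_target_is_smallest_group(self):
        adata = self._three_groups()
        out = balanced_subsample(adata, seed=1)
        assert set(out.obs["condition"].value_counts()) == {120}

    def test_same_seed_reproducible_and_truthful(self):
        adata = self._three_groups()
        out1 = balanced_subsample(adata, seed=7)
        out2 = balanced_subsample(adata, seed=7)
        assert list(out1.obs_names) == list(out2.obs_names)
        assert set(out1.obs_names) <= set(adata.obs_names)

    def test_oversized_target_names_group(self):
        adata = self._three_groups()
        with pytest.raises(ValueError, match="mi"):
            balanced_subsample(adata, target_size=200, seed=1)


class TestRankTest:
    def test_complete_separation_matches_enumeration_oracle(self):
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = rank_test_pair(np.array(x), np.array(y))
        # oracle: enumerate all rank assignments of 3 of 6 positions
        values = sorted(x + y)
        obs_stat = sum(values.index(v) + 1 for v in x)
        stats = [sum(c) for c in combinations(range(1, 7), 3)]
        mean_stat = np.mean(stats)
        extreme = sum(abs(s - mean_stat) >= abs(obs_stat - mean_stat) for s in stats)
        assert p == pytest.approx(extreme / len(stats))

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(4)
        sig = 0
        for _ in range(300):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            sig += rank_test_pair(x, y) < 0.05
        assert sig / 300 <= 0.06  # ~5% nominal

    def test_constant_groups_p_one(self):
        assert rank_test_pair(np.zeros(5), np.zeros(5)) == 1.0

    def test_pairwise_over_conditions_and_empty_group_error(self):
        X = np.vstack([np.full((3, 1), 1.0), np.full((3, 1), 10.0), np.full((3, 1), 5.0)])
        adata = _adata(X, conditions=["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        out = groupwise_rank_test(adata, "g0")
        assert len(out) == 3
        assert set(out.columns) == {"group_a", "group_b", "p_value"}
        with pytest.raises(KeyError):
            groupwise_rank_test(adata, "missing_gene")
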