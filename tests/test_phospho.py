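import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from math import comb

from ersecretome.phospho import (
    DEFAULT_MOTIFS,
    KinaseMotif,
    activity_to_frame,
    cluster_sites,
    filter_sites,
    impute_missing,
    infer_kinase_activity,
    linkage_to_newick,
    load_motifs,
    match_motif,
    project_pca,
    protein_purity,
    responsive_sites,
    site_regulation,
)
from ersecretome.simulate import default_design, simulate_phospho

from conftest import make_phospho_table


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive two-tail hypergeometric sum over tables with fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = {k: comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFilterSites:
    def _table(self):
        design = default_design()
        X = np.full((3, 24), 20.0)
        table = make_phospho_table(X)
        table.sites.loc["s0000", "loc_prob"] = 0.6  # confidently localized? no
        # s0001: complete only in control-5min; missing everywhere else
        X = table.intensity.to_numpy()
        ctrl5 = [i for i, s in enumerate(design.index) if s.startswith("control_5min")]
        X[1, :] = np.nan
        X[1, ctrl5] = 20.0
        # s0002: at most 3/4 in every group
        X[2, ::4] = np.nan
        table.intensity = pd.DataFrame(X, index=table.intensity.index,
                                       columns=table.intensity.columns)
        return table

    def test_low_localization_probability_removed(self):
        out = filter_sites(self._table())
        assert "s0000" not in out.sites.index

    def test_complete_in_one_group_retained(self):
        out = filter_sites(self._table())
        assert "s0001" in out.sites.index

    def test_incomplete_everywhere_removed(self):
        out = filter_sites(self._table())
        assert "s0002" not in out.sites.index


class TestImputation:
    def test_downshifted_normal_moments(self):
        # measured {10,12,14}: mu=12, sigma=2 -> imputed ~ Normal(8.4, 0.6)
        n = 20003
        col = np.full((n, 1), np.nan)
        col[:3, 0] = [10.0, 12.0, 14.0]
        design = default_design(replicates=1).iloc[:1]
        table = make_phospho_table(col, design=design)
        out = impute_missing(table, seed=3)
        vals = out.intensity.iloc[3:, 0].to_numpy()
        assert vals.mean() == pytest.approx(8.4, abs=0.05)
        assert vals.std(ddof=1) == pytest.approx(0.6, abs=0.05)
        ks = st.kstest(vals, "norm", args=(8.4, 0.6))
        assert ks.pvalue > 0.01

    def test_measured_values_never_altered(self, phospho_sim):
        table, _ = phospho_sim
        filtered = filter_sites(table)
        out = impute_missing(filtered, seed=1)
        measured = filtered.intensity.notna()
        before = filtered.intensity.to_numpy()[measured.to_numpy()]
        after = out.intensity.to_numpy()[measured.to_numpy()]
        np.testing.assert_array_equal(before, after)
        assert not out.intensity.isna().any().any()

    def test_no_missing_is_identity(self):
        X = np.random.default_rng(0).normal(20, 1, (5, 24))
        table = make_phospho_table(X)
        out = impute_missing(table, seed=9)
        np.testing.assert_array_equal(out.intensity.to_numpy(), X)

    def test_same_seed_bitwise_identical(self, phospho_sim):
        table, _ = phospho_sim
        filtered = filter_sites(table)
        a = impute_missing(filtered, seed=5).intensity.to_numpy()
        b = impute_missing(filtered, seed=5).intensity.to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_single_measured_value_rejected(self):
        col = np.full((4, 1), np.nan)
        col[0, 0] = 20.0
        design = default_design(replicates=1).iloc[:1]
        with pytest.raises(ValueError, match="at least 2"):
            impute_missing(make_phospho_table(col, design=design), seed=0)


class TestResponsiveSites:
    def test_constant_site_not_responsive(self):
        X = np.full((2, 24), 20.0)
        out = responsive_sites(make_phospho_table(X))
        assert not out["responsive"].any()
        assert (out["p_value"] == 1.0).all()

    def test_shifted_site_detected(self):
        rng = np.random.default_rng(8)
        detected = 0
        for _ in range(10):
            X = rng.normal(20, 0.3, (1, 24))
            X[0, :4] += 2.0  # +2 log2 in the first group
            out = responsive_sites(make_phospho_table(X))
            detected += int(out["responsive"].iloc[0])
        assert detected == 10

    def test_degenerate_different_means_p_zero(self):
        X = np.repeat([[1.0] * 4 + [2.0] * 20], 2, axis=0)
        out = responsive_sites(make_phospho_table(X))
        assert (out["p_value"] == 0.0).all()


class TestPCA:
    def test_separated_conditions_split_on_pc1(self):
        rng = np.random.default_rng(2)
        X = rng.normal(20, 0.2, (50, 24))
        design = default_design()
        stim = [i for i, s in enumerate(design.index) if not s.startswith("control")]
        X[:25, stim] += 3.0
        scores, _ = project_pca(pd.DataFrame(
            X, index=[f"s{i}" for i in range(50)], columns=design.index))
        pc1 = scores["PC1"]
        ctrl = pc1[[s.startswith("control") for s in scores.index]]
        rest = pc1[[not s.startswith("control") for s in scores.index]]
        assert ctrl.max() < rest.min() or rest.max() < ctrl.min()

    def test_duplicated_sample_identical_scores(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 6))
        X[:, 5] = X[:, 4]
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(10)],
                             columns=[f"c{i}" for i in range(6)])
        scores, _ = project_pca(frame)
        np.testing.assert_allclose(scores.loc["c4"], scores.loc["c5"], atol=1e-10)

    def test_explained_variance_conserved(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 8))
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(30)],
                             columns=[f"c{i}" for i in range(8)])
        _, explained = project_pca(frame, n_components=3)
        total = np.var(X.T, axis=0, ddof=1).sum()
        assert explained.sum() == pytest.approx(total, rel=1e-8)
        assert (np.diff(explained) <= 1e-12).all()


class TestClustering:
    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[5.0, 5.0], [0.0, 0.0], [5.0, 5.0]])
        frame = pd.DataFrame(X, index=["a", "b", "c"], columns=["x", "y"])
        Z, _ = cluster_sites(frame)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_three_point_toy_matches_hand_ward(self):
        frame = pd.DataFrame({"v": [0.0, 1.0, 10.0]}, index=["a", "b", "c"])
        Z, order = cluster_sites(frame)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)  # singleton Ward = Euclidean
        # Ward merge of {0,1} with {10}: sqrt((2*10^2 + 2*9^2 - 1^2)/3)
        assert Z[1, 2] == pytest.approx(np.sqrt((2 * 100 + 2 * 81 - 1) / 3))

    def test_permutation_invariant_heights_and_newick(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 4))
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(12)],
                             columns=list("wxyz"))
        Z1, order1 = cluster_sites(frame)
        perm = rng.permutation(12)
        Z2, order2 = cluster_sites(frame.iloc[perm])
        np.testing.assert_allclose(np.sort(Z1[:, 2]), np.sort(Z2[:, 2]), atol=1e-10)
        nwk = linkage_to_newick(Z1, list(frame.index))
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(12))


class TestMotifMatching:
    AKT = KinaseMotif("AKT", {-5: frozenset("R"), -3: frozenset("R")}, frozenset("ST"))

    def test_akt_flank_matches(self):
        assert match_motif("AARARAASAAAAAAA", self.AKT)

    def test_center_tyrosine_rejected(self):
        assert not match_motif("AARARAAYAAAAAAA", self.AKT)

    def test_padding_never_satisfies_constraint(self):
        motif = KinaseMotif("K", {-7: frozenset("_R")}, frozenset("S"))
        assert not match_motif("_AAAAAASAAAAAAA", motif)

    def test_malformed_flank_rejected(self):
        with pytest.raises(ValueError):
            match_motif("SHORT", self.AKT)

    def test_against_brute_force_checker(self):
        rng = np.random.default_rng(6)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY_"))
        for _ in range(2000):
            flank = "".join(rng.choice(alphabet, size=15))
            for motif in DEFAULT_MOTIFS[:4]:
                # independent position-by-position check
                expected = flank[7] in motif.center
                for off, allowed in motif.constraints.items():
                    ch = flank[7 + off]
                    expected = expected and (ch != "_") and (ch in allowed)
                assert match_motif(flank, motif) == expected

    def test_registry_round_trip_via_tsv(self, tmp_path):
        path = tmp_path / "motifs.tsv"
        path.write_text(
            "kinase\toffset\tallowed\tcenter\n"
            "AKT\t-5\tR\tST\nAKT\t-3\tR\tST\nSRC\t-3\tDE\tY\nSRC\t1\tDE\tY\n"
        )
        motifs = load_motifs(path)
        assert [m.kinase for m in motifs] == ["AKT", "SRC"]
        assert motifs[1].center == frozenset("Y")
        assert match_motif("AARARAASAAAAAAA", motifs[0])


class TestKinaseActivity:
    def test_fisher_p_matches_enumeration_oracle(self):
        _, p = st.fisher_exact([[8, 2], [10, 80]])
        assert p == pytest.approx(fisher_two_sided_oracle(8, 2, 10, 80), rel=1e-9)

    def test_planted_kinase_uniquely_recovered(self):
        table, truth = simulate_phospho(seed=42)
        imputed = impute_missing(filter_sites(table), seed=43)
        results = infer_kinase_activity(imputed, DEFAULT_MOTIFS, "CRELD2", 5)
        sig = [r for r in results if r.significant]
        assert [r.kinase for r in sig] == ["AMPK"]
        assert sig[0].mean_regulation > 0
        assert all(t in truth.target_sites["AMPK"] for t in sig[0].targets)
        a, b, c, d = sig[0].contingency
        assert a + b + c + d == imputed.n_sites

    def test_bh_rejection_set_is_p_threshold_rule(self):
        table, _ = simulate_phospho(seed=13)
        imputed = impute_missing(filter_sites(table), seed=14)
        results = infer_kinase_activity(imputed, DEFAULT_MOTIFS, "CRELD2", 5)
        pvals = sorted(r.fisher_p for r in results)
        m = len(pvals)
        # BH: the rejection set equals {p <= max p_(k) with p_(k) <= q k/m}
        thresh = max((p for k, p in enumerate(pvals, 1) if p <= 0.02 * k / m),
                     default=-1.0)
        for r in results:
            assert r.significant == (r.fisher_p <= thresh)
            assert 0.0 <= r.fdr <= 1.0

    def test_end_to_end_determinism(self):
        frames = []
        for _ in range(2):
            table, _ = simulate_phospho(seed=99)
            imputed = impute_missing(filter_sites(table), seed=100)
            frames.append(activity_to_frame(
                infer_kinase_activity(imputed, DEFAULT_MOTIFS, "CRELD2", 5)))
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_unimputed_table_rejected(self, phospho_sim):
        table, _ = phospho_sim
        with pytest.raises(ValueError, match="imputed"):
            site_regulation(filter_sites(table), "CRELD2", 5)


class TestProteinPurity:
    @pytest.mark.parametrize(
        "target,contaminant,expected",
        [(97.7, 2.3, 97.7), (50.0, 0.0, 100.0), (0.0, 10.0, 0.0)],
    )
    def test_purity_fraction(self, target, contaminant, expected):
        df = pd.DataFrame(
            {"intensity": [target, contaminant], "is_target": [True, False]}
        )
        assert protein_purity(df) == pytest.approx(expected)

    def test_zero_total_is_missing(self):
        df = pd.DataFrame({"intensity": [0.0], "is_target": [True]})
        assert np.isnan(protein_purity(df))
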