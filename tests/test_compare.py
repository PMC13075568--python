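import numpy as np
import pandas as pd
import pytest

from capnet._util import default_mirror_pairs
from capnet.compare import (
    SimilarityMatrix,
    beta_consistency_correlation,
    consistency_mixed_model,
    consistency_table,
    dice_score,
    fisher_z,
    loo_consistency,
    match_maps,
    permutation_match_test,
    similarity_confusion,
    symmetry_index,
    temporal_correspondence,
)


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_odd_function(self, rng):
        r = rng.uniform(-0.99, 0.99, 20)
        np.testing.assert_allclose(fisher_z(r), -fisher_z(-r))

    def test_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-10)

    def test_monotone(self):
        grid = np.linspace(-0.999, 0.999, 101)
        assert np.all(np.diff(fisher_z(grid)) > 0)

    def test_clipping_warns(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestDice:
    def test_identical_maps(self, rng):
        m = rng.uniform(0.1, 1.0, 20)
        assert dice_score(m, m) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = np.array([1.0, 1.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 1.0, 1.0])
        assert dice_score(a, b) == 0.0

    def test_hand_example(self):
        a = np.array([1.0, 0.3, 0.1, 0.0])
        b = np.array([0.5, 0.05, 0.4, 0.2])
        assert dice_score(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_empty_binarized_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            d = dice_score(np.array([-1.0, -2.0]), np.array([1.0, 2.0]))
        assert d == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            dice_score(np.ones(3), np.ones(4))


class TestSimilarityConfusion:
    def test_self_comparison_diagonal(self, rng):
        maps = rng.standard_normal((4, 30))
        out = similarity_confusion(maps, maps, match_table=[(i, i) for i in range(4)])
        np.testing.assert_allclose(np.diag(out["dice"].values), 1.0)
        z = out["fisher_z"].values
        assert np.all(np.argmax(z, axis=1) == np.arange(4))

    def test_matches_looped_recomputation(self, rng):
        for _ in range(5):
            caps = rng.standard_normal((3, 25))
            rsns = rng.standard_normal((5, 25))
            out = similarity_confusion(caps, rsns)
            for i in range(3):
                for j in range(5):
                    r = np.corrcoef(caps[i], rsns[j])[0, 1]
                    assert out["fisher_z"].values[i, j] == pytest.approx(np.arctanh(r))
                    assert out["dice"].values[i, j] == pytest.approx(
                        dice_score(caps[i], rsns[j])
                    )

    def test_hemisphere_restricted_beats_whole_map(self):
        # left-dominant map vs its bilateral partner: restrict to the left
        half = 10
        left_pat = np.array([2.0, 1.5, 1.0, 0.5, 0.2, 0.1, 0.4, 0.3, 0.9, 1.2])
        unilateral = np.concatenate([left_pat, 0.05 * np.ones(half)])
        bilateral = np.concatenate([left_pat, left_pat])
        masks = {"L": np.arange(20) < half}
        out_whole = similarity_confusion(unilateral[None], bilateral[None],
                                         match_table=[(0, 0)])
        out_hemi = similarity_confusion(unilateral[None], bilateral[None],
                                        match_table=[(0, 0, "L")],
                                        hemisphere_masks=masks)
        assert out_hemi["fisher_z"].values[0, 0] > out_whole["fisher_z"].values[0, 0]

    def test_missing_id_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            similarity_confusion(rng.standard_normal((2, 10)),
                                 rng.standard_normal((2, 10)),
                                 match_table=[(0, 5)])

    def test_hungarian_matching_recovers_permutation(self, rng):
        maps = rng.standard_normal((5, 40))
        perm = np.array([3, 0, 4, 1, 2])
        pairs = match_maps(maps, maps[perm])
        assert {(i, j) for i, j in pairs} == {(int(perm[j]), int(j)) for j in range(5)}


class TestPermutationTest:
    def test_observed_beats_all_nulls(self):
        # identity relabeling is permitted but essentially never drawn at
        # 8 columns (p = 1/8! per draw), so every null mean is strictly lower
        V = np.eye(8) * 5.0
        sim = SimilarityMatrix(V, "fisher_z", [(i, i) for i in range(8)])
        out = permutation_match_test(sim, n_perm=1000, seed=0)
        assert out.p_matched_mean == pytest.approx(1.0 / 1001)

    def test_constant_matrix_p_near_one(self):
        V = np.full((3, 3), 0.5)
        sim = SimilarityMatrix(V, "fisher_z", [(i, i) for i in range(3)])
        out = permutation_match_test(sim, n_perm=500, seed=1)
        assert out.p_matched_mean == pytest.approx(1.0)

    def test_low_n_perm_refused(self):
        sim = SimilarityMatrix(np.eye(3), "dice", [(0, 0)])
        with pytest.raises(ValueError):
            permutation_match_test(sim, n_perm=50)

    def test_per_pair_pvalues_present_and_bonferroni(self):
        V = np.eye(3)
        pairs = [(i, i) for i in range(3)]
        out = permutation_match_test(SimilarityMatrix(V, "dice", pairs),
                                     n_perm=200, seed=2)
        for p in pairs:
            assert out.p_per_pair_corrected[p] >= out.p_per_pair[p]


class TestSymmetry:
    def test_symmetric_map_is_one(self, rng):
        pairs = default_mirror_pairs(12)
        half = rng.standard_normal(6)
        v = np.concatenate([half, half])
        assert symmetry_index(v, pairs) == pytest.approx(1.0)

    def test_antisymmetric_map_is_minus_one(self, rng):
        pairs = default_mirror_pairs(12)
        half = rng.standard_normal(6)
        v = np.concatenate([half, -half])
        assert symmetry_index(v, pairs) == pytest.approx(-1.0)

    def test_random_maps_mean_near_zero(self, rng):
        pairs = default_mirror_pairs(40)
        vals = [symmetry_index(rng.standard_normal(40), pairs) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.05

    def test_unilateral_pair_uses_partner(self, rng):
        pairs = default_mirror_pairs(10)
        half = rng.standard_normal(5)
        left = np.concatenate([half, 0.1 * half])
        right = np.concatenate([0.1 * half, half])  # exact mirror of left
        assert symmetry_index(left, pairs, partner=right) == pytest.approx(1.0)

    def test_synthetic_bilateral_templates_exactly_one(self, small_templates):
        ts = small_templates
        for i, spec in enumerate(ts.mirror_spec):
            if spec == "bilateral":
                assert symmetry_index(ts.templates[i], ts.mirror_pairs) == pytest.approx(1.0)

    def test_odd_roi_count_rejected(self):
        with pytest.raises(ValueError):
            symmetry_index(np.ones(5), np.array([[0, 1]]))


class TestLooConsistency:
    def test_identical_participants(self, rng):
        m = np.tile(rng.standard_normal(15), (5, 1))
        np.testing.assert_allclose(loo_consistency(m), 1.0)

    def test_orthogonal_outlier(self):
        # odd has zero correlation with shared (orthogonal after centering)
        shared = np.array([1.0, 0, 1, 0, 1, 0, 1, 0])
        odd = np.array([1.0, 1, 0, 0, 1, 1, 0, 0])
        M = np.vstack([shared] * 9 + [odd])
        r = loo_consistency(M)
        assert np.all(r[:9] > 0.99)
        assert abs(r[9]) < 0.1

    def test_agrees_with_naive_loop(self, rng):
        M = rng.standard_normal((6, 20))
        r = loo_consistency(M)
        for i in range(6):
            others = np.delete(M, i, axis=0).mean(axis=0)
            assert r[i] == pytest.approx(np.corrcoef(M[i], others)[0, 1])

    def test_needs_three_participants(self, rng):
        with pytest.raises(ValueError):
            loo_consistency(rng.standard_normal((2, 5)))

    def test_missing_participant_nan(self, rng):
        M = rng.standard_normal((4, 10))
        M[2] = np.nan
        r = loo_consistency(M)
        assert np.isnan(r[2]) and np.isfinite(r[0])


class TestMixedModel:
    @staticmethod
    def planted_table(effects=(0.9, 0.7, 0.5), sd=0.05, n=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        intercepts = 0.05 * rng.standard_normal(n)
        for g, mu in zip(["SM", "HO", "Other"], effects):
            for pat in range(3):
                for p in range(n):
                    rows.append(
                        {"pattern": f"{g}{pat}", "pattern_type": "CAP", "group": g,
                         "participant": p,
                         "z": mu + intercepts[p] + sd * rng.standard_normal()}
                    )
        return pd.DataFrame(rows)

    def test_flat_data_no_contrasts(self):
        df = self.planted_table(effects=(0.7, 0.7, 0.7), sd=0.05, seed=3)
        out = consistency_mixed_model(df)
        coef = out["coefficients"]
        group_rows = [i for i in coef.index if "group" in i]
        assert all(coef.loc[i, "p"] > 0.01 for i in group_rows)

    def test_planted_gradient_significant(self):
        df = self.planted_table(effects=(0.9, 0.7, 0.5), sd=0.05, n=20, seed=4)
        out = consistency_mixed_model(df)
        coef = out["coefficients"]
        group_rows = [i for i in coef.index if "group" in i]
        assert len(group_rows) == 2
        assert all(coef.loc[i, "p"] < 0.01 for i in group_rows)
        assert all(coef.loc[i, "beta"] < 0 for i in group_rows)  # SM is reference

    def test_random_intercept_variance_recovered(self):
        rng = np.random.default_rng(5)
        n = 30
        intercepts = 0.3 * rng.standard_normal(n)
        rows = []
        for g in ["SM", "HO", "Other"]:
            for pat in range(4):
                for p in range(n):
                    rows.append({"pattern": f"{g}{pat}", "pattern_type": "CAP",
                                 "group": g, "participant": p,
                                 "z": 0.5 + intercepts[p] + 0.1 * rng.standard_normal()})
        out = consistency_mixed_model(pd.DataFrame(rows))
        assert not out["fallback_ols"]
        est_var = float(out["fit"].cov_re.iloc[0, 0])
        assert 0.5 * 0.09 < est_var < 1.5 * 0.09

    def test_consistency_table_shape(self, rng):
        maps = {f"c{i}": rng.standard_normal((5, 12)) for i in range(3)}
        groups = {f"c{i}": "SM" for i in range(3)}
        tab = consistency_table(maps, groups, "CAP")
        assert set(tab.columns) >= {"pattern", "group", "participant", "z"}
        assert len(tab) == 15


class TestBetaConsistency:
    def test_proportional_gives_r_one(self, rng):
        G = rng.uniform(0.5, 1.0, (3, 40))
        L = rng.uniform(0.2, 0.9, (3, 6))
        B = np.zeros((3, 6, 40))
        for c in range(3):
            for p in range(6):
                B[c, p, :] = L[c, p]  # mean beta inside any mask == consistency
        out = beta_consistency_correlation(B, G, L)
        assert out["r"] == pytest.approx(1.0)

    def test_independent_inputs_small_r(self, rng):
        rs = []
        for _ in range(100):
            B = rng.standard_normal((3, 5, 30))
            G = rng.standard_normal((3, 30))
            L = rng.uniform(0, 1, (3, 5))
            rs.append(beta_consistency_correlation(B, G, L)["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_hand_four_points(self):
        B = np.zeros((1, 4, 2))
        B[0, :, 0] = [1.0, 2.0, 3.0, 4.0]
        B[0, :, 1] = -99  # outside the top mask
        G = np.array([[1.0, 0.0]])
        L = np.array([[0.2, 0.1, 0.5, 0.4]])
        out = beta_consistency_correlation(B, G, L, mask_frac=0.5)
        expected = np.corrcoef([1, 2, 3, 4], [0.2, 0.1, 0.5, 0.4])[0, 1]
        assert out["r"] == pytest.approx(expected)

    def test_degenerate_inputs_missing(self):
        B = np.ones((1, 4, 3))
        G = np.ones((1, 3))
        L = np.full((1, 4), 0.5)
        out = beta_consistency_correlation(B, G, L)
        assert np.isnan(out["r"])


class TestTemporalCorrespondence:
    def test_identical_series_r_one(self, rng):
        tc = rng.standard_normal((2, 300))
        out = temporal_correspondence([tc], [tc], match_table=[(0, 0), (1, 1)],
                                      n_perm=200, seed=0)
        assert out.values[0, 0] > 5  # fisher z of r ~= 1 is huge

    def test_independent_series_mean_z_near_zero(self, rng):
        zs = []
        for _ in range(100):
            a = rng.standard_normal((1, 200))
            b = rng.standard_normal((2, 200))
            out = temporal_correspondence([a], [b], match_table=[(0, 0)],
                                          n_perm=100, seed=1)
            zs.append(out.values[0, 0])
        assert abs(np.mean(zs)) < 0.02

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            temporal_correspondence([rng.standard_normal((1, 100))],
                                    [rng.standard_normal((1, 90))],
                                    match_table=[(0, 0)], n_perm=100)

    def test_matched_pair_dominates_on_planted_link(self, rng):
        drive = rng.standard_normal(500)
        cap_tc = np.vstack([drive + 0.2 * rng.standard_normal(500),
                            rng.standard_normal(500)])
        ic_env = np.vstack([drive + 0.2 * rng.standard_normal(500),
                            rng.standard_normal(500),
                            rng.standard_normal(500)])
        out = temporal_correspondence([cap_tc], [ic_env], match_table=[(0, 0)],
                                      n_perm=500, seed=3)
        assert out.values[0, 0] > out.values[0, 1:].max()
        assert out.values[0, 0] > out.values[1, :].max()
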