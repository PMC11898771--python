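import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from conftest import make_table
from _oracles import emd_lp_oracle, emd_permutation_oracle
from morphoscreen.io_tables import FeatureTable
from morphoscreen.profiling import (
    DissimilarityMatrix,
    cluster_conditions,
    condition_dissimilarity,
    embed_2d,
    screen_features,
    wasserstein_1d,
    zscore_features,
)


# ------------------------------------------------------------------ z-score
class TestZScore:
    def test_three_point_example(self):
        t = make_table(conditions=("A",), n_images=1, n_cells=3, n_features=1,
                       feature_values=lambda cond, im, cid, f: float(cid))
        z, dropped = zscore_features(t)
        np.testing.assert_allclose(
            np.sort(z.data["feat_0"].to_numpy()),
            [-1.22474487, 0.0, 1.22474487],
        )
        assert dropped == []

    def test_constant_feature_dropped_and_named(self):
        t = make_table(n_features=2,
                       feature_values=lambda cond, im, cid, f: 5.0 if f == 0 else float(cid))
        with pytest.warns(UserWarning, match="feat_0"):
            z, dropped = zscore_features(t)
        assert dropped == ["feat_0"]
        assert z.feature_columns == ("feat_1",)

    def test_pooled_moments_after_zscore(self):
        t = make_table(n_features=3, seed=4)
        z, _ = zscore_features(t)
        feats = z.features().to_numpy()
        np.testing.assert_allclose(feats.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(feats.std(axis=0), 1.0, atol=1e-12)

    def test_all_constant_errors(self):
        t = make_table(n_features=1, feature_values=lambda *a: 3.0)
        with pytest.raises(ValueError, match="zero variance"):
            zscore_features(t)


# ---------------------------------------------------------------------- EMD
class TestWasserstein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0.0, 0.0, 0.0], [0.0, 0.0, 0.0], 0.0),
            ([0.0, 1.0], [2.0, 3.0], 2.0),
            ([0.0, 0.0], [3.0], 3.0),
            ([1.0], [4.0], 3.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert wasserstein_1d(a, b) == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])

    def test_matches_permutation_oracle_equal_sizes(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 9))
            a = rng.normal(size=n) * rng.uniform(0.5, 3.0)
            b = rng.normal(size=n) + rng.uniform(-2, 2)
            assert wasserstein_1d(a, b) == pytest.approx(
                emd_permutation_oracle(a, b), abs=1e-9
            )

    def test_matches_lp_oracle_unequal_sizes(self, rng):
        for _ in range(30):
            n, m = int(rng.integers(1, 13)), int(rng.integers(1, 13))
            a, b = rng.normal(size=n), rng.normal(scale=2.0, size=m)
            assert wasserstein_1d(a, b) == pytest.approx(
                emd_lp_oracle(a, b), abs=1e-9
            )

    def test_matches_scipy_reference(self, rng):
        for _ in range(30):
            a = rng.gamma(2.0, 1.5, size=int(rng.integers(2, 200)))
            b = rng.normal(size=int(rng.integers(2, 200)))
            assert wasserstein_1d(a, b) == pytest.approx(
                sps.wasserstein_distance(a, b), rel=1e-12, abs=1e-12
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        x=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        c=st.floats(-1e6, 1e6),
    )
    def test_translation_identity(self, x, c):
        x = np.asarray(x)
        assert wasserstein_1d(x, x + c) == pytest.approx(abs(c), rel=1e-9, abs=1e-9)

    def test_zscore_makes_emd_scale_free(self, rng):
        # same data, one feature multiplied by 1000 -> identical per-feature EMDs
        t = make_table(n_features=1, seed=8)
        scaled = t.data.copy()
        scaled["feat_0"] *= 1000.0
        t2 = FeatureTable(scaled)
        za, _ = zscore_features(t)
        zb, _ = zscore_features(t2)
        va, _ = condition_dissimilarity(za, min_cells=10)
        vb, _ = condition_dissimilarity(zb, min_cells=10)
        np.testing.assert_allclose(va[0].distances, vb[0].distances, rtol=1e-12)


# ------------------------------------------------------------ dissimilarity
class TestDissimilarity:
    def test_3_4_5_aggregation(self):
        # two features whose per-feature EMDs are exactly 3 and 4
        def values(cond, im, cid, f):
            base = 0.0 if cond == "A" else (3.0 if f == 0 else 4.0)
            return base + 0.001 * cid  # spread, identical in both conditions

        t = make_table(n_images=1, n_cells=60, n_features=2, feature_values=values)
        vectors, D = condition_dissimilarity(t, min_cells=10)
        np.testing.assert_allclose(vectors[0].distances, [3.0, 4.0], atol=1e-12)
        assert D[("A", "B")] == pytest.approx(5.0, abs=1e-12)

    def test_duplicated_condition_distance_zero(self):
        def values(cond, im, cid, f):
            return float(cid)  # same cells relabelled

        t = make_table(n_images=1, n_cells=60, n_features=3, feature_values=values)
        _, D = condition_dissimilarity(t, min_cells=10)
        assert D[("A", "B")] == 0.0

    def test_min_cells_exclusion(self):
        t = make_table(conditions=("A", "B", "C"), n_images=1, n_cells=60, seed=1)
        small = t.data[~((t.data.condition == "C") & (t.data.cell_id > 5))]
        t2 = FeatureTable(small.reset_index(drop=True))
        with pytest.warns(UserWarning, match="excluded"):
            _, D = condition_dissimilarity(t2, min_cells=50)
        assert D.conditions == ("A", "B")
        t3 = FeatureTable(t.data[t.data.cell_id <= 5].reset_index(drop=True))
        with pytest.raises(ValueError, match="at least two conditions"):
            with pytest.warns(UserWarning):
                condition_dissimilarity(t3, min_cells=50)

    def test_matrix_is_metric_on_random_tables(self, rng):
        for trial in range(10):
            t = make_table(conditions=("A", "B", "C", "D"), n_images=1,
                           n_cells=30, n_features=3, seed=trial)
            _, D = condition_dissimilarity(t, min_cells=10)
            v = D.values
            assert np.allclose(v, v.T) and np.allclose(np.diag(v), 0.0)
            n = len(D.conditions)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert v[i, j] <= v[i, k] + v[k, j] + 1e-12

    def test_gaussian_shift_recovered(self, rng):
        # EMD between N(0,1) and N(delta,1) is |delta| in expectation
        rows = []
        for cond, delta in (("ref", 0.0), ("s1", 1.0), ("s2", 2.0)):
            for cid in range(2000):
                rows.append({"cell_id": cid, "image_id": f"{cond}_i0",
                             "condition": cond, "f": rng.normal(delta, 1.0)})
        t = FeatureTable(pd.DataFrame(rows))
        _, D = condition_dissimilarity(t, min_cells=50)
        assert D[("ref", "s1")] == pytest.approx(1.0, rel=0.15)
        assert D[("ref", "s2")] > D[("ref", "s1")]


# ---------------------------------------------------------------- embedding
class TestEmbedding:
    def test_planar_configuration_recovered(self, rng):
        X = rng.normal(size=(4, 2)) * 3.0
        D = DissimilarityMatrix(tuple("abcd"), squareform(pdist(X)))
        emb = embed_2d(D)
        d_emb = squareform(pdist(emb.coordinates))
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs(d_emb[off] - D.values[off]) / D.values[off]) < 1e-6
        # Procrustes alignment of the embedding onto the generator coordinates
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(X, emb.coordinates)
        assert disparity < 1e-12

    def test_equilateral_from_equal_distances(self):
        v = np.ones((3, 3)) - np.eye(3)
        emb = embed_2d(DissimilarityMatrix(("a", "b", "c"), v))
        d = pdist(emb.coordinates)
        np.testing.assert_allclose(d, d[0], rtol=1e-9)
        np.testing.assert_allclose(d[0], 1.0, rtol=1e-9)

    def test_duplicated_condition_coincident(self):
        v = np.array(
            [[0.0, 0.0, 5.0, 4.0],
             [0.0, 0.0, 5.0, 4.0],
             [5.0, 5.0, 0.0, 3.0],
             [4.0, 4.0, 3.0, 0.0]]
        )
        emb = embed_2d(DissimilarityMatrix(tuple("aabc"), v))
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-6)

    def test_too_few_conditions(self):
        with pytest.raises(ValueError):
            embed_2d(DissimilarityMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_smacof_deterministic_given_seed(self, rng):
        X = rng.normal(size=(6, 2))
        D = DissimilarityMatrix(tuple("abcdef"), squareform(pdist(X)))
        e1 = embed_2d(D, method="smacof", seed=3)
        e2 = embed_2d(D, method="smacof", seed=3)
        np.testing.assert_array_equal(e1.coordinates, e2.coordinates)
        assert e1.stress < 0.05


# ---------------------------------------------------------------- screening
class TestScreen:
    def _image_mean_table(self, groups):
        # one feature; image means are exactly the provided group values
        rows = []
        for cond, values in groups.items():
            for j, v in enumerate(values):
                for cid in (1, 2):
                    rows.append({"cell_id": cid, "image_id": f"{cond}_i{j}",
                                 "condition": cond, "f": float(v)})
        return FeatureTable(pd.DataFrame(rows))

    def test_hand_computed_H(self):
        t = self._image_mean_table({"A": [1, 2, 3], "B": [4, 5, 6]})
        out = screen_features(t)
        assert out.loc[0, "H"] == pytest.approx(3.857142857, abs=1e-6)
        assert out.loc[0, "p"] == pytest.approx(0.0495, abs=1e-3)

    def test_all_tied_degenerate(self):
        t = self._image_mean_table({"A": [2, 2, 2], "B": [2, 2, 2]})
        out = screen_features(t)
        assert out.loc[0, "H"] == 0.0 and out.loc[0, "p"] == 1.0

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            samples = [rng.normal(size=8) for _ in range(3)]
            _, p = sps.kruskal(*samples)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_single_group_errors(self):
        t = self._image_mean_table({"A": [1, 2, 3]})
        with pytest.raises(ValueError):
            screen_features(t)

    def test_q_at_least_p_and_flags(self):
        t = make_table(conditions=("A", "B", "C"), n_images=4, n_features=5, seed=2)
        out = screen_features(t)
        assert (out["q"] >= out["p"] - 1e-15).all()
        assert out["significant"].equals(out["q"] < 0.05)


# --------------------------------------------------------------- clustering
class TestClustering:
    def test_two_separated_groups_recovered(self, rng):
        X = np.vstack([rng.normal(0.0, 0.1, (5, 3)), rng.normal(10.0, 0.1, (5, 3))])
        frame = pd.DataFrame(X, index=[f"c{i}" for i in range(10)])
        res = cluster_conditions(frame)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.linkage, t=2, criterion="maxclust")
        assert adjusted_rand_score([0] * 5 + [1] * 5, labels) == 1.0

    def test_identical_rows_merge_first(self):
        frame = pd.DataFrame(
            [[1.0, 1.0], [1.0, 1.0], [9.0, 9.0]], index=["a", "b", "c"]
        )
        res = cluster_conditions(frame)
        assert res.linkage[0, 2] == 0.0  # first merge at height zero
        assert sorted(res.linkage[0, :2]) == [0.0, 1.0]

    def test_leaf_order_is_permutation(self, rng):
        t = make_table(conditions=("A", "B", "C", "D"), n_images=1, n_cells=30, seed=3)
        _, D = condition_dissimilarity(t, min_cells=10)
        res = cluster_conditions(D)
        assert sorted(res.leaf_order) == sorted(D.conditions)

    def test_non_finite_rejected(self):
        frame = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="non-finite"):
            cluster_conditions(frame)
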