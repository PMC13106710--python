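"""Feature assembly, correlation-distance WPGMA clustering, PCA, stability."""

import numpy as np
import pandas as pd
import pytest

from flypheno import phenotype_clustering as pc


def brute_force_wpgma(dist):
    """Reference WPGMA: clusters merge at the average of pairwise parent
    distances, new distances are plain means of the two merged clusters'."""
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = {i: (i,) for i in range(n)}
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        others = [k for k in active if k not in (i, j)]
        for k in others:
            a = d[tuple(sorted((i, k)))]
            b = d[tuple(sorted((j, k)))]
            d[tuple(sorted((next_id, k)))] = 0.5 * (a + b)
        active[next_id] = active.pop(i) + active.pop(j)
        d = {key: v for key, v in d.items()
             if key[0] in active and key[1] in active}
        next_id += 1
    return heights


@pytest.fixture
def planted_matrix(rng):
    """12 genotypes, two groups separated by >=1 sd on several features."""
    base = rng.normal(0, 0.3, (12, 6))
    base[:6, :3] += 2.0
    base[6:, 3:] += 2.0
    return pd.DataFrame(base, index=[f"g{i}" for i in range(12)],
                        columns=[f"f{i}" for i in range(6)])


class TestAssembleFeatures:
    def _inputs(self):
        feats = pd.DataFrame(
            {"sleep_fraction_day": [1.0, 2.0, 3.0],
             "morning_anticipation": [0.5, 0.6, 0.7],
             "velocity_if_awake": [3.0, 2.0, 1.0]},
            index=["g1", "g2", "g3"])
        comp = pd.DataFrame({"NMF0": [0.1, 0.5, 0.9]}, index=["g1", "g2", "g3"])
        return feats, comp

    def test_zscore_uses_sample_sd(self):
        feats, comp = self._inputs()
        out = pc.assemble_features(feats, comp)
        np.testing.assert_allclose(out["sleep_fraction_day"], [-1, 0, 1])

    def test_morning_anticipation_excluded(self):
        feats, comp = self._inputs()
        out = pc.assemble_features(feats, comp)
        assert "morning_anticipation" not in out.columns
        assert "NMF0" in out.columns

    def test_constant_column_rejected(self):
        feats, comp = self._inputs()
        comp["NMF0"] = 1.0
        with pytest.raises(ValueError):
            pc.assemble_features(feats, comp)

    def test_mismatched_genotypes_named(self):
        feats, comp = self._inputs()
        with pytest.raises(ValueError, match="g3"):
            pc.assemble_features(feats, comp.drop(index=["g3"]))


class TestCorrelationDistance:
    def test_identical_rows_distance_zero(self):
        rows = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        d = pc.correlation_distance(rows)
        assert d[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_rows_distance_two(self):
        rows = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert pc.correlation_distance(rows)[0, 1] == pytest.approx(2.0)

    def test_hand_pearson(self):
        rows = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        assert pc.correlation_distance(rows)[0, 1] == pytest.approx(0.5)

    def test_zero_variance_row_rejected(self):
        with pytest.raises(ValueError):
            pc.correlation_distance(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


class TestWPGMA:
    def test_hand_example(self):
        dist = np.array([[0.0, 1.0, 4.0],
                         [1.0, 0.0, 5.0],
                         [4.0, 5.0, 0.0]])
        tree = pc.wpgma_linkage(dist, ["a", "b", "c"])
        np.testing.assert_allclose(tree.Z[:, 2], [1.0, 4.5])

    def test_equal_distances_equal_heights(self):
        dist = np.ones((4, 4)) - np.eye(4)
        tree = pc.wpgma_linkage(dist, list("abcd"))
        assert np.allclose(tree.Z[:, 2], 1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = rng.random((6, 4))
            dist = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            tree = pc.wpgma_linkage(dist, [f"l{i}" for i in range(6)])
            np.testing.assert_allclose(tree.Z[:, 2], brute_force_wpgma(dist),
                                       rtol=1e-10)

    def test_monotone_heights_on_ultrametric(self):
        # ultrametric: nested clusters at heights 1 and 2
        dist = np.array([[0, 1, 2, 2],
                         [1, 0, 2, 2],
                         [2, 2, 0, 1],
                         [2, 2, 1, 0]], dtype=float)
        tree = pc.wpgma_linkage(dist, list("abcd"))
        heights = tree.Z[:, 2]
        assert np.all(np.diff(heights) >= 0)

    def test_newick_roundtrip_readable(self):
        import io
        import skbio
        dist = np.array([[0.0, 1.0, 4.0],
                         [1.0, 0.0, 5.0],
                         [4.0, 5.0, 0.0]])
        tree = pc.wpgma_linkage(dist, ["a", "b", "c"])
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {t.name for t in parsed.tips()} == {"a", "b", "c"}


class TestCutTree:
    def test_extremes(self, planted_matrix):
        dist = pc.correlation_distance(planted_matrix.to_numpy())
        tree = pc.wpgma_linkage(dist, list(planted_matrix.index))
        singles = pc.cut_tree(tree, 12)
        assert len(set(singles.values())) == 12
        one = pc.cut_tree(tree, 1)
        assert set(one.values()) == {1}

    def test_planted_two_groups_recovered(self, planted_matrix):
        scaled = pc.scale_columns(planted_matrix)
        _, groups, _ = pc.cluster_genotypes(scaled, n_groups=2, n_subgroups=4)
        left = {g for g, c in groups.items() if c == groups["g0"]}
        assert left in ({f"g{i}" for i in range(6)},
                        {f"g{i}" for i in range(6, 12)})

    def test_row_order_invariance(self, planted_matrix):
        scaled = pc.scale_columns(planted_matrix)
        _, groups, _ = pc.cluster_genotypes(scaled)
        shuffled = scaled.sample(frac=1.0, random_state=1)
        _, groups2, _ = pc.cluster_genotypes(shuffled)
        same = {frozenset(g for g, c in p.items() if c == v)
                for p in (groups, groups2) for v in set(p.values())}
        assert len(same) == 2


class TestPCA:
    def test_variance_fractions_sum_to_one(self, planted_matrix):
        res = pc.pca(pc.scale_columns(planted_matrix))
        assert res.variance_fraction.sum() == pytest.approx(1.0)

    def test_collinear_data_single_component(self):
        x = np.linspace(0, 1, 8)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        res = pc.pca(df)
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_cor2_of_pc_aligned_feature_is_one(self, rng):
        df = pd.DataFrame(rng.normal(0, 1, (10, 3)), columns=list("abc"))
        df["d"] = df["a"] * 3.0          # perfectly correlated with a
        res = pc.pca(pc.scale_columns(df))
        # feature d correlates with some PC exactly as a does
        np.testing.assert_allclose(res.cor2.loc["a"], res.cor2.loc["d"],
                                   atol=1e-8)
        assert res.cor2.to_numpy().max() <= 1.0 + 1e-9


class TestStability:
    def test_noise_column_drop_keeps_partition(self, rng):
        # four well-separated planted subgroups, three genotypes each
        raw = pd.DataFrame(rng.normal(0, 0.2, (12, 8)),
                           index=[f"g{i}" for i in range(12)],
                           columns=[f"f{i}" for i in range(8)])
        for grp in range(4):
            raw.iloc[grp * 3:(grp + 1) * 3, 2 * grp:2 * grp + 2] += 2.5
        raw["noise"] = rng.normal(0, 1.0, len(raw))
        scaled = pc.scale_columns(raw)
        _, _, ref = pc.cluster_genotypes(scaled, n_subgroups=4)
        out = pc.stability_loo(raw, ref, n_subgroups=4)
        dropped_noise = out[out["dropped"] == "noise"]
        assert (dropped_noise["jaccard"] == 1.0).all()
        assert (dropped_noise["category"] == "0.7-1").all()

    def test_reference_against_itself_high(self, planted_matrix):
        scaled = pc.scale_columns(planted_matrix)
        _, _, ref = pc.cluster_genotypes(scaled, n_subgroups=4)
        scores = pc.best_match_jaccard(ref, ref)
        assert all(v == 1.0 for v in scores.values())
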