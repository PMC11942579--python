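import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ginqc import SimilarityMatrix, pairwise_similarity, upgma, within_batch_similarity

from conftest import make_band_matrix


def _pair_matrix(row_a, row_b):
    return make_band_matrix(
        [("A", row_a), ("B", row_b)],
        [f"p:{k}" for k in range(len(row_a))],
        {"A": "b", "B": "b"},
    )


class TestPairwiseSimilarity:
    def test_hand_enumerated_pair(self):
        # 10110 vs 10011: a=2, b=1, c=1, d=1
        bm = _pair_matrix([1, 0, 1, 1, 0], [1, 0, 0, 1, 1])
        assert pairwise_similarity(bm, "simple_matching").values.loc["A", "B"] == pytest.approx(0.6)
        assert pairwise_similarity(bm, "dice").values.loc["A", "B"] == pytest.approx(4 / 6)
        assert pairwise_similarity(bm, "jaccard").values.loc["A", "B"] == pytest.approx(0.5)

    @pytest.mark.parametrize("method", ["simple_matching", "dice", "jaccard"])
    def test_identical_profiles_give_one(self, method):
        bm = _pair_matrix([1, 0, 1], [1, 0, 1])
        assert pairwise_similarity(bm, method).values.loc["A", "B"] == pytest.approx(1.0)

    @pytest.mark.parametrize("method,expected", [("dice", 0.0), ("jaccard", 0.0)])
    def test_complementary_profiles(self, method, expected):
        bm = _pair_matrix([1, 1, 0, 0], [0, 0, 1, 1])
        assert pairwise_similarity(bm, method).values.loc["A", "B"] == pytest.approx(expected)

    def test_two_empty_profiles_defined_as_identical(self):
        bm = make_band_matrix(
            [("A", [0, 0]), ("B", [0, 0]), ("C", [1, 1])],
            ["p:1", "p:2"],
            {"A": "b", "B": "b", "C": "b"},
        )
        with pytest.warns(UserWarning, match="all-zero"):
            sim = pairwise_similarity(bm, "dice")
        assert sim.values.loc["A", "B"] == pytest.approx(1.0)

    def test_unknown_method_rejected(self, small_bm):
        with pytest.raises(ValueError, match="coefficient"):
            pairwise_similarity(small_bm, "cosine")

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.integers(0, 1), min_size=6, max_size=6),
            min_size=3,
            max_size=6,
        ),
        method=st.sampled_from(["simple_matching", "dice", "jaccard"]),
    )
    def test_symmetry_unit_diagonal_and_range(self, data, method):
        import warnings

        rows = [(f"s{i}", r) for i, r in enumerate(data)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-zero rows/columns are legal here
            bm = make_band_matrix(
                rows, [f"p:{k}" for k in range(6)], {f"s{i}": "b" for i in range(len(data))}
            )
            sim = pairwise_similarity(bm, method).values.to_numpy()
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)
        assert ((sim >= 0) & (sim <= 1)).all()

    def test_permuting_samples_permutes_values(self, study_like_bm):
        sim = pairwise_similarity(study_like_bm, "dice").values
        rng = np.random.default_rng(3)
        perm = rng.permutation(study_like_bm.values.index)
        shuffled = make_band_matrix(
            [(s, study_like_bm.values.loc[s].to_numpy()) for s in perm],
            study_like_bm.band_ids,
            study_like_bm.batch_map.to_dict(),
        )
        sim2 = pairwise_similarity(shuffled, "dice").values
        pd.testing.assert_frame_equal(sim2.loc[sim.index, sim.columns], sim)


def _sim_from_dist(ids, dist):
    d = np.asarray(dist, dtype=float)
    return SimilarityMatrix(pd.DataFrame(1 - d, index=ids, columns=ids), "dice")


class TestUpgma:
    def test_three_taxon_hand_oracle(self):
        # d(A,B)=0.1, d(A,C)=d(B,C)=0.4 -> merge {A,B} at height 0.05, C at 0.2
        sim = _sim_from_dist(
            ["A", "B", "C"],
            [[0, 0.1, 0.4], [0.1, 0, 0.4], [0.4, 0.4, 0]],
        )
        dend = upgma(sim)
        assert dend.merge_heights == pytest.approx([0.05, 0.2])
        tree = dend.tree
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        ab = tree.lca([tree.find("A"), tree.find("B")])
        assert tree.find("A").accumulate_to_ancestor(ab) == pytest.approx(0.05)

    def test_ultrametricity_on_random_matrix(self, study_like_bm):
        sim = pairwise_similarity(study_like_bm, "dice")
        dend = upgma(sim)
        depths = [tip.accumulate_to_ancestor(dend.tree) for tip in dend.tree.tips()]
        assert np.allclose(depths, depths[0])
        assert (np.diff(dend.merge_heights) >= -1e-12).all()

    def test_idempotent_on_ultrametric_input(self, study_like_bm):
        sim = pairwise_similarity(study_like_bm, "dice")
        first = upgma(sim)
        coph = first.cophenetic_distances()
        again = upgma(SimilarityMatrix(1 - coph, "dice"))
        pd.testing.assert_frame_equal(
            again.cophenetic_distances(), coph, check_exact=False, atol=1e-12
        )

    def test_deterministic_under_full_ties(self):
        ids = ["x", "a", "m"]
        sim = _sim_from_dist(ids, 0.3 * (1 - np.eye(3)))
        dend = upgma(sim)
        # lexicographic tie-break: the first merge joins 'a' and 'm'
        internal = [c for c in dend.tree.children if not c.is_tip()]
        assert len(internal) == 1
        assert sorted(t.name for t in internal[0].tips()) == ["a", "m"]

    def test_two_cluster_structure_recovered(self):
        rng = np.random.default_rng(11)
        founders = {"X": np.r_[np.ones(20), np.zeros(20)], "Y": np.r_[np.zeros(20), np.ones(20)]}
        rows = []
        for group, founder in founders.items():
            for i in range(3):
                profile = founder.copy()
                flip = rng.choice(40, size=2, replace=False)
                profile[flip] = 1 - profile[flip]
                rows.append((f"{group}{i}", profile.astype(int)))
        bm = make_band_matrix(
            rows, [f"p:{k}" for k in range(40)],
            {f"{c}{i}": c for c in "XY" for i in range(3)},
        )
        dend = upgma(pairwise_similarity(bm, "dice"))
        # cutting below the root (largest merge gap) yields the two batches
        left, right = dend.tree.children
        groups = [
            {t.name[0] for t in side.tips(include_self=True)} for side in (left, right)
        ]
        assert sorted(groups, key=sorted) == [{"X"}, {"Y"}]

    def test_rejects_single_sample(self):
        sim = SimilarityMatrix(pd.DataFrame([[1.0]], index=["A"], columns=["A"]), "dice")
        with pytest.raises(ValueError, match="2 samples"):
            upgma(sim)


class TestWithinBatch:
    def test_hand_mean_and_sd(self):
        ids = ["a", "b", "c"]
        vals = pd.DataFrame(
            [[1.0, 0.9, 0.8], [0.9, 1.0, 0.7], [0.8, 0.7, 1.0]], index=ids, columns=ids
        )
        out = within_batch_similarity(
            SimilarityMatrix(vals, "dice"), {s: "B" for s in ids}
        )
        assert out.loc["B", "mean"] == pytest.approx(0.8)
        assert out.loc["B", "sd"] == pytest.approx(0.1)
        assert out.loc["B", "n_pairs"] == 3

    def test_identical_samples_mean_one_sd_zero(self):
        bm = make_band_matrix(
            [("a", [1, 0, 1]), ("b", [1, 0, 1]), ("c", [1, 0, 1])],
            ["p:1", "p:2", "p:3"],
            {"a": "B", "b": "B", "c": "B"},
        )
        out = within_batch_similarity(pairwise_similarity(bm, "dice"), bm.batch_map)
        assert out.loc["B", "mean"] == pytest.approx(1.0)
        assert out.loc["B", "sd"] == pytest.approx(0.0)

    def test_singleton_batch_excluded_with_warning(self, small_bm):
        sim = pairwise_similarity(small_bm, "dice")
        bmap = {"s1": "b1", "s2": "b1", "s3": "solo", "s4": "other"}
        with pytest.warns(UserWarning, match="<2 samples"):
            out = within_batch_similarity(sim, bmap)
        assert "solo" not in out.index and "b1" in out.index

    def test_heterogeneity_orders_batch_means(self, study_like_bm):
        sim = pairwise_similarity(study_like_bm, "dice")
        out = within_batch_similarity(sim, study_like_bm.batch_map)
        # generating flip rates: GG 0.01 (tightest) ... FG 0.12 (loosest)
        assert out.loc["GG", "mean"] > out.loc["PG03", "mean"] > out.loc["FG", "mean"] - 0.2
        assert out.loc["GG", "mean"] > out.loc["FG", "mean"]
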