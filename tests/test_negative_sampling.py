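import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensemble_mfp.dataset_io import PairFeatureBlock, assemble_pair_vectors, enumerate_pairs
from ensemble_mfp.negative_sampling import (
    build_union_pool,
    distance_rank,
    positive_centroid,
    sample_from_pool,
    select_negatives,
)
from ensemble_mfp.pipeline import _euclidean_selection

from conftest import random_block


def block_of(matrix, pairs=None, fp_id="fp1"):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if pairs is None:
        pairs = [(f"d{i:03d}", f"t{i:03d}") for i in range(matrix.shape[0])]
    return PairFeatureBlock(pairs, matrix, fp_id)


class TestPositiveCentroid:
    def test_mean_of_two_points(self):
        c = positive_centroid(block_of([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_array_equal(c, [1.0, 1.0])

    def test_single_row_is_its_own_centroid(self):
        np.testing.assert_array_equal(
            positive_centroid(block_of([[3.0, -1.0]])), [3.0, -1.0]
        )

    def test_matches_summation_oracle(self, rng):
        b = random_block(rng, 100, 7)
        oracle = np.array(
            [sum(b.matrix[i, j] for i in range(100)) / 100.0 for j in range(7)]
        )
        np.testing.assert_allclose(positive_centroid(b), oracle, atol=1e-12)

    def test_zero_positives_error(self):
        with pytest.raises(ValueError, match="positive"):
            positive_centroid(block_of(np.empty((0, 3))))


class TestDistanceRank:
    def test_three_four_five_triangle(self):
        b = block_of([[3.0, 4.0], [1.0, 0.0]])
        r = distance_rank(b, np.zeros(2))
        np.testing.assert_allclose(r.distances, [5.0, 1.0])
        assert r.pairs[0] == ("d000", "t000")

    def test_point_at_centroid_ranked_last(self, rng):
        m = np.vstack([rng.normal(size=(5, 3)) + 10, np.zeros(3)])
        r = distance_rank(block_of(m), np.zeros(3))
        assert r.distances[-1] == 0.0
        assert r.pairs[-1] == ("d005", "t005")

    def test_matches_brute_force_sort(self, rng):
        """Full ranking identical to an exhaustive sort of per-point distances."""
        b = random_block(rng, 200, 6)
        centroid = rng.normal(size=6)
        r = distance_rank(b, centroid)
        dist = {
            p: float(np.sqrt(((centroid - row) ** 2).sum()))
            for p, row in zip(b.pairs, b.matrix)
        }
        oracle = sorted(b.pairs, key=lambda p: (-dist[p], p))
        assert r.pairs == oracle

    def test_ties_broken_by_ascending_pair_id(self):
        pairs = [("dB", "t1"), ("dA", "t1"), ("dA", "t0")]
        r = distance_rank(block_of(np.ones((3, 2)), pairs), np.zeros(2))
        assert r.pairs == [("dA", "t0"), ("dA", "t1"), ("dB", "t1")]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-50, 50))
    def test_translation_invariance(self, seed, shift):
        """Adding a constant vector to points and centroid preserves the ranking."""
        g = np.random.default_rng(seed)
        b = random_block(g, 30, 4)
        centroid = g.normal(size=4)
        shifted = block_of(b.matrix + shift, list(b.pairs))
        assert distance_rank(b, centroid).pairs == distance_rank(shifted, centroid + shift).pairs

    def test_dimension_mismatch_error(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            distance_rank(random_block(rng, 5, 3), np.zeros(4))


class TestSelectNegatives:
    def test_all_and_single(self, rng):
        b = random_block(rng, 10, 3)
        r = distance_rank(b, np.zeros(3))
        assert set(select_negatives(r, 10)) == set(b.pairs)
        assert select_negatives(r, 1) == [r.pairs[0]]

    def test_overdraw_reports_both_counts(self, rng):
        r = distance_rank(random_block(rng, 5, 2), np.zeros(2))
        with pytest.raises(ValueError, match="6.*5"):
            select_negatives(r, 6)

    def test_planted_outliers_recovered_exactly(self, tiny_benchmark):
        """With well-separated planted negatives, the top of every feature
        pair's ranking is exactly the planted set."""
        b = tiny_benchmark
        idx = enumerate_pairs(b.interactions)
        planted = set(b.truth.planted_negatives)
        for fp in b.feature_pair_ids:
            block = assemble_pair_vectors(idx, b.drug_tables[fp], b.target_tables[fp], fp)
            sel = _euclidean_selection(block, idx.labels, len(planted), 0.95, "minmax")
            assert set(sel) == planted


class TestUnionPool:
    def test_idempotent_union(self):
        sel = [("d1", "t1"), ("d2", "t2")]
        pool = build_union_pool({"fp1": sel, "fp2": sel, "fp3": sel})
        assert sorted(pool.pairs) == sorted(sel)
        assert pool.provenance[("d1", "t1")] == ["fp1", "fp2", "fp3"]

    def test_disjoint_lists_sum(self):
        sels = {f"fp{i}": [(f"d{i}", f"t{j}") for j in range(4)] for i in range(3)}
        assert len(build_union_pool(sels)) == 12

    def test_overlap_matches_set_oracle(self, rng):
        universe = [(f"d{i}", f"t{j}") for i in range(6) for j in range(6)]
        sels = {
            f"fp{k}": [universe[i] for i in rng.choice(36, 12, replace=False)]
            for k in range(3)
        }
        pool = build_union_pool(sels)
        assert set(pool.pairs) == set().union(*map(set, sels.values()))
        assert max(map(len, sels.values())) <= len(pool) <= sum(map(len, sels.values()))


class TestSampleFromPool:
    def pool(self, n=10):
        return build_union_pool({"fp1": [(f"d{i}", "t0") for i in range(n)]})

    def test_full_draw_returns_entire_pool(self):
        p = self.pool()
        assert sorted(sample_from_pool(p, 10, seed=3)) == sorted(p.pairs)

    def test_same_seed_identical(self):
        p = self.pool()
        assert sample_from_pool(p, 4, seed=9) == sample_from_pool(p, 4, seed=9)

    def test_uniformity(self):
        """Each of 10 elements drawn with frequency 0.1 +/- 0.02 over 10k draws."""
        p = self.pool()
        counts = {pair: 0 for pair in p.pairs}
        for s in range(10_000):
            counts[sample_from_pool(p, 1, seed=s)[0]] += 1
        freqs = np.array(list(counts.values())) / 10_000
        assert (np.abs(freqs - 0.1) < 0.02).all()

    def test_overdraw_error(self):
        with pytest.raises(ValueError, match="pool"):
            sample_from_pool(self.pool(3), 4, seed=0)
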