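import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ensemble_mfp.dataset_io import PairFeatureBlock
from ensemble_mfp.ensemble_model import (
    DEFAULT_C,
    DEFAULT_GAMMA,
    SubModelConfig,
    SubModelScores,
    decision_values,
    ensemble_decision,
    enumerate_weight_grid,
    optimize_weights,
    train_submodel,
)


def block_of(matrix, fp_id="fp1"):
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    pairs = [(f"d{i:03d}", f"t{i:03d}") for i in range(matrix.shape[0])]
    return PairFeatureBlock(pairs, matrix, fp_id)


@pytest.fixture
def separable_block(rng):
    x = np.vstack([rng.normal(size=(20, 2)) + 4, rng.normal(size=(20, 2)) - 4])
    y = np.r_[np.ones(20, int), -np.ones(20, int)]
    return block_of(x), y


def scores_of(values, fp_id="fp1", n=None):
    values = np.asarray(values, dtype=float)
    pairs = [(f"d{i:03d}", f"t{i:03d}") for i in range(len(values))]
    return SubModelScores(pairs, values, fp_id)


class TestTrainSubmodel:
    def test_separable_clusters_get_correct_signs(self, separable_block):
        block, y = separable_block
        # the default gamma is tuned for higher-dimensional pair vectors; on
        # a 2-D toy a unit gamma keeps the kernel informative
        m = train_submodel(block, y, SubModelConfig("fp1", c=1.0, gamma=1.0))
        dec = decision_values(m, block).values
        assert (np.sign(dec) == y).all()

    def test_defaults_recorded_in_metadata(self, separable_block):
        block, y = separable_block
        m = train_submodel(block, y, SubModelConfig("fp2"))
        assert m.config.c == DEFAULT_C == 2.0**-4
        assert m.config.gamma == DEFAULT_GAMMA == 2.0**-7
        assert (m.n_positive, m.n_negative) == (20, 20)
        assert m.n_features == 2

    def test_retraining_is_deterministic(self, separable_block):
        block, y = separable_block
        cfg = SubModelConfig("fp1")
        d1 = decision_values(train_submodel(block, y, cfg), block).values
        d2 = decision_values(train_submodel(block, y, cfg), block).values
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_single_class_error(self, separable_block):
        block, _ = separable_block
        with pytest.raises(ValueError, match="both classes"):
            train_submodel(block, np.ones(block.n_pairs, int), SubModelConfig("fp1"))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SubModelConfig("fp1", c=-1.0)


class TestDecisionValues:
    def test_empty_block_gives_empty_vector(self, separable_block):
        block, y = separable_block
        m = train_submodel(block, y, SubModelConfig("fp1"))
        out = decision_values(m, block_of(np.empty((0, 2))))
        assert out.values.shape == (0,)

    def test_permutation_equivariance(self, rng, separable_block):
        block, y = separable_block
        m = train_submodel(block, y, SubModelConfig("fp1"))
        perm = rng.permutation(block.n_pairs)
        permuted = PairFeatureBlock(
            [block.pairs[i] for i in perm], block.matrix[perm], "fp1"
        )
        np.testing.assert_allclose(
            decision_values(m, permuted).values,
            decision_values(m, block).values[perm],
            atol=1e-12,
        )

    def test_dimension_mismatch_error(self, separable_block):
        block, y = separable_block
        m = train_submodel(block, y, SubModelConfig("fp1"))
        with pytest.raises(ValueError, match="features"):
            decision_values(m, block_of(np.zeros((3, 5))))


class TestEnsembleDecision:
    def test_corner_weight_is_identity(self, rng):
        scores = [scores_of(rng.normal(size=10), f"fp{i}") for i in range(3)]
        np.testing.assert_array_equal(
            ensemble_decision((1.0, 0.0, 0.0), scores), scores[0].values
        )

    def test_linearity(self):
        scores = [scores_of(v) for v in ([3, 0, 0], [0, 3, 0], [0, 0, 3])]
        np.testing.assert_allclose(
            ensemble_decision((1 / 3, 1 / 3, 1 / 3), scores), [1.0, 1.0, 1.0]
        )

    def test_matches_elementwise_accumulation(self, rng):
        w = rng.dirichlet(np.ones(3))
        scores = [scores_of(rng.normal(size=25), f"fp{i}") for i in range(3)]
        oracle = np.array(
            [sum(w[i] * scores[i].values[k] for i in range(3)) for k in range(25)]
        )
        np.testing.assert_allclose(ensemble_decision(w, scores), oracle, atol=1e-12)

    def test_pair_mismatch_error(self, rng):
        s1 = scores_of(rng.normal(size=5))
        s2 = SubModelScores(list(reversed(s1.pairs)), s1.values, "fp2")
        with pytest.raises(ValueError, match="different pairs"):
            ensemble_decision((0.5, 0.5), [s1, s2])

    def test_invalid_weights_rejected(self, rng):
        scores = [scores_of(rng.normal(size=5), f"fp{i}") for i in range(2)]
        with pytest.raises(ValueError, match="sum to 1"):
            ensemble_decision((0.5, 0.6), scores)


class TestWeightGrid:
    def test_step_half_enumerable_by_hand(self):
        grid = set(enumerate_weight_grid(0.5))
        assert grid == {
            (1, 0, 0), (0, 1, 0), (0, 0, 1),
            (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5),
        }

    def test_step_tenth_has_66_points_with_corners(self):
        grid = enumerate_weight_grid(0.1)
        assert len(grid) == 66
        for corner in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            assert corner in [tuple(map(round, g)) for g in grid] or corner in grid

    def test_all_points_on_simplex(self):
        for w in enumerate_weight_grid(0.1):
            assert abs(sum(w) - 1.0) < 1e-9
            assert all(0 <= wi <= 1 for wi in w)

    def test_invalid_steps_rejected(self):
        for bad in (0.0, -0.1, 1.5, 0.3):
            with pytest.raises(ValueError):
                enumerate_weight_grid(bad)


class TestOptimizeWeights:
    def make_scores(self, rng, n=40, noise_scale=50.0):
        # noise sub-models are loud: any admixture of them breaks the perfect
        # model's ranking, so only the corner weight attains AUC 1.0
        y = np.r_[np.ones(n // 2, int), -np.ones(n // 2, int)]
        perfect = scores_of(y + 0.01 * rng.normal(size=n), "fp1")
        noise1 = scores_of(noise_scale * rng.normal(size=n), "fp2")
        noise2 = scores_of(noise_scale * rng.normal(size=n), "fp3")
        return [perfect, noise1, noise2], y

    def test_corner_dominance(self, rng):
        scores, y = self.make_scores(rng)
        w, best = optimize_weights(scores, y, step=0.1)
        assert best == 1.0
        assert w == (1.0, 0.0, 0.0)

    def test_identical_models_return_first_grid_point(self, rng):
        v = rng.normal(size=20)
        y = np.where(v > 0, 1, -1)
        scores = [scores_of(v, f"fp{i}") for i in range(3)]
        w, _ = optimize_weights(scores, y, step=0.1)
        assert w == enumerate_weight_grid(0.1)[0]

    def test_matches_exhaustive_oracle(self):
        """Returned AUC equals the max over all 66 grid points computed with an
        independent AUC implementation."""
        for seed in range(5):
            g = np.random.default_rng(seed)
            y = g.choice([-1, 1], size=30)
            while len(np.unique(y)) < 2:
                y = g.choice([-1, 1], size=30)
            scores = [scores_of(g.normal(size=30), f"fp{i}") for i in range(3)]
            _, best = optimize_weights(scores, y, step=0.1)
            oracle = max(
                roc_auc_score(y, sum(wi * s.values for wi, s in zip(w, scores)))
                for w in enumerate_weight_grid(0.1)
            )
            assert best == pytest.approx(oracle, abs=1e-12)

    def test_validation_auc_at_least_best_individual(self, rng):
        """Corner property: the grid contains each single sub-model."""
        for _ in range(5):
            y = rng.choice([-1, 1], size=30)
            while len(np.unique(y)) < 2:
                y = rng.choice([-1, 1], size=30)
            scores = [scores_of(rng.normal(size=30), f"fp{i}") for i in range(3)]
            _, best = optimize_weights(scores, y, step=0.1)
            assert best >= max(roc_auc_score(y, s.values) for s in scores) - 1e-12

    def test_invariant_under_joint_monotone_transform(self, rng):
        scores, y = self.make_scores(rng)
        w1, a1 = optimize_weights(scores, y, step=0.5)
        transformed = [
            SubModelScores(s.pairs, np.exp(s.values), s.feature_pair_id) for s in scores
        ]
        w2, a2 = optimize_weights(transformed, y, step=0.5)
        assert a2 == pytest.approx(a1, abs=1e-12)

    def test_single_class_labels_error(self, rng):
        scores = [scores_of(rng.normal(size=5), f"fp{i}") for i in range(3)]
        with pytest.raises(ValueError, match="both classes"):
            optimize_weights(scores, np.ones(5, int))
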