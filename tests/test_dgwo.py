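import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fasf_tle.dgwo import (
    ClassificationErrorFitness,
    DGWOSelector,
    binarize_position,
    dgwo_select,
    dto_fly_update,
    dto_swim_update,
    exhaustive_best_mask,
    fitness_classification_error,
    gwo_step,
)
from fasf_tle.synth import FeatureSpec, make_feature_dataset
from fasf_tle.types import FeatureTable


class ConstantRng:
    """Deterministic stand-in drawing a fixed value, for hand oracles."""

    def __init__(self, value):
        self.value = value

    def random(self, shape=None):
        return np.full(shape, self.value) if shape is not None else self.value


class TestSwimUpdate:
    def test_best_is_fixed_point(self):
        best = np.array([0.8, 0.3])
        out = dto_swim_update(best.copy(), best, c1=1.3, c2=1.0)
        np.testing.assert_allclose(out, best)

    def test_one_dimensional_hand_example(self):
        out = dto_swim_update(np.array([0.2]), np.array([0.8]), c1=1.0, c2=1.0)
        np.testing.assert_allclose(out, [0.2])

    def test_c1_zero_collapses_to_best(self):
        out = dto_swim_update(np.array([0.1, 0.9]), np.array([0.5, 0.5]),
                              c1=0.0, c2=1.7)
        np.testing.assert_allclose(out, [0.5, 0.5])


class TestFlyUpdate:
    def test_global_optimum_is_fixed_point(self):
        p = np.array([0.4])
        speed, pos = dto_fly_update(p, np.zeros(1), p, p, 0.9, 1.5, 1.5, 0.7)
        np.testing.assert_allclose(speed, [0.0])
        np.testing.assert_allclose(pos, p)

    def test_one_dimensional_hand_example(self):
        speed, pos = dto_fly_update(
            np.array([0.2]), np.array([0.1]), np.array([0.5]), np.array([0.8]),
            c3=0.9, c4=1.5, c5=1.5, r1=0.5,
        )
        np.testing.assert_allclose(speed, [0.765], atol=1e-12)
        np.testing.assert_allclose(pos, [0.965], atol=1e-12)

    def test_zero_inertia_and_draw_freeze_agent(self):
        speed, pos = dto_fly_update(
            np.array([0.3]), np.array([0.2]), np.array([0.9]), np.array([0.9]),
            c3=0.0, c4=1.5, c5=1.5, r1=0.0,
        )
        np.testing.assert_allclose(speed, [0.0])
        np.testing.assert_allclose(pos, [0.3])


class TestGwoStep:
    def test_hand_example_with_fixed_draws(self):
        out = gwo_step(np.array([[0.2]]), np.array([[0.6], [0.6], [0.6]]),
                       l=1.0, rng=ConstantRng(0.5))
        np.testing.assert_allclose(out, [[0.6]])

    def test_coincident_leaders_and_zero_l_collapse(self):
        rng = np.random.default_rng(0)
        out = gwo_step(np.array([[0.1], [0.9]]), np.full((3, 1), 0.7), l=0.0,
                       rng=rng)
        np.testing.assert_allclose(out, [[0.7], [0.7]])

    def test_positions_stay_in_unit_cube(self):
        rng = np.random.default_rng(1)
        pos = rng.random((6, 4))
        out = gwo_step(pos, rng.random((3, 4)), l=2.0, rng=rng)
        assert np.all((out >= 0) & (out <= 1))

    def test_requires_three_leaders(self):
        with pytest.raises(ValueError, match="3 leaders"):
            gwo_step(np.zeros((2, 2)), np.zeros((2, 2)), 1.0,
                     np.random.default_rng(0))


class TestBinarize:
    def test_strict_threshold(self):
        np.testing.assert_array_equal(
            binarize_position(np.array([0.2, 0.5, 0.8]), 0.5), [0, 0, 1]
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.float64, 6, elements=st.floats(0, 1)),
           st.floats(0.1, 0.45), st.floats(0.55, 0.9))
    def test_raising_threshold_never_adds_features(self, pos, lo, hi):
        low = binarize_position(pos, lo)
        high = binarize_position(pos, hi)
        assert np.all(high <= low)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            binarize_position(np.array([0.5]), 1.0)


@pytest.fixture(scope="module")
def planted():
    ds = make_feature_dataset(FeatureSpec(n_per_class=30, n_informative=2,
                                          n_noise=8, effect_size=4.0, seed=1))
    return ds, ClassificationErrorFitness(ds.table)


class TestFitness:
    def test_separable_single_feature_zero_error(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(-1, 0.01, 30), rng.normal(1, 0.01, 30)])
        table = FeatureTable([f"s{i}" for i in range(60)], ["f0"],
                             values[:, None], np.repeat([0, 1], 30))
        assert fitness_classification_error(np.array([1]), table) == 0.0

    def test_empty_mask_scores_one(self, planted):
        _, ev = planted
        assert ev(np.zeros(10, dtype=int)) == 1.0

    def test_single_class_rejected(self):
        table = FeatureTable(["a", "b"], ["f"], np.zeros((2, 1)), np.array([1, 1]))
        with pytest.raises(ValueError, match="two classes"):
            ClassificationErrorFitness(table)

    def test_noise_features_cannot_push_error_negative(self, planted):
        ds, ev = planted
        perfect = np.zeros(10, dtype=int)
        perfect[ds.informative_columns] = 1
        assert ev(np.ones(10, dtype=int)) >= 0.0
        assert ev(perfect) >= 0.0


class TestSelection:
    def test_best_mask_beats_all_features(self, planted):
        ds, ev = planted
        res = dgwo_select(ds.table, seed=1, evaluator=ev)
        assert res.best_fitness <= ev(np.ones(10, dtype=int))

    def test_trace_is_monotone_best_so_far(self, planted):
        ds, ev = planted
        res = dgwo_select(ds.table, seed=2, evaluator=ev)
        assert np.all(np.diff(res.fitness_trace) <= 0)

    def test_deterministic_given_seed(self, planted):
        ds, ev = planted
        a = dgwo_select(ds.table, seed=3, evaluator=ev)
        b = dgwo_select(ds.table, seed=3, evaluator=ev)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.best_fitness == b.best_fitness
        assert a.fitness_trace == b.fitness_trace

    def test_near_exhaustive_optimum_across_seeds(self, planted):
        ds, ev = planted
        _, best = exhaustive_best_mask(ds.table, ev)
        wins = sum(
            dgwo_select(ds.table, seed=s, evaluator=ev).best_fitness <= best + 0.02
            for s in range(10)
        )
        assert wins >= 8

    def test_selector_sklearn_surface(self, planted):
        ds, _ = planted
        sel = DGWOSelector(n_agents=6, max_iter=10, random_state=0).fit(
            ds.table.values, ds.table.labels
        )
        assert sel.support_.shape == (10,)
        assert sel.transform(ds.table.values).shape[1] == sel.n_selected_
        params = sel.get_params()
        assert params["n_agents"] == 6

    def test_agent_floor(self, planted):
        ds, _ = planted
        with pytest.raises(ValueError, match="4 agents"):
            DGWOSelector(n_agents=3).fit(ds.table.values, ds.table.labels)


class TestExhaustive:
    def test_single_informative_feature_found(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        X[:20, 1] -= 3
        X[20:, 1] += 3
        table = FeatureTable([f"s{i}" for i in range(40)], ["a", "b", "c"], X,
                             np.repeat([0, 1], 20))
        mask, fit = exhaustive_best_mask(table)
        np.testing.assert_array_equal(mask, [0, 1, 0])

    def test_tie_resolved_to_fewer_features(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(-2, 0.01, 20), rng.normal(2, 0.01, 20)])
        X = np.stack([x, x], axis=1)  # duplicated informative feature
        table = FeatureTable([f"s{i}" for i in range(40)], ["a", "b"], X,
                             np.repeat([0, 1], 20))
        mask, _ = exhaustive_best_mask(table)
        assert mask.sum() == 1 and mask[0] == 1

    def test_oracle_never_worse_than_search(self, planted):
        ds, ev = planted
        _, best = exhaustive_best_mask(ds.table, ev)
        res = dgwo_select(ds.table, seed=0, evaluator=ev)
        assert best <= res.best_fitness

    def test_refuses_large_dimension(self):
        table = FeatureTable(["s"], [f"f{i}" for i in range(17)],
                             np.zeros((1, 17)), np.array([0]))
        with pytest.raises(ValueError, match="refused"):
            exhaustive_best_mask(table)
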